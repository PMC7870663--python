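measure,mean_reported,sd_reported,mean_lit,sd_lit,decimals,source
scc_ant_height,6.4,0.5,6.5,0.5,1,ref35
scc_ant_width,8.2,0.5,8.0,0.5,1,ref35
scc_ant_radius,3.7,0.2,3.6,0.2,1,ref35
scc_post_height,7.0,0.6,6.7,0.6,1,ref35
scc_post_width,7.7,0.6,7.7,0.5,1,ref35
scc_post_radius,3.7,0.3,3.6,0.2,1,ref35
scc_lat_height,5.0,0.4,4.9,0.6,1,ref35
scc_lat_width,6.6,0.4,6.5,0.7,1,ref35
scc_lat_radius,2.9,0.2,2.9,0.3,1,ref35
common_crus_length,2.3,0.2,2.0,0.5,1,ref35
common_crus_width_1,2.2,0.2,1.6,0.3,1,ref35
common_crus_width_2,1.9,0.2,1.5,0.3,1,ref35
common_crus_width_3,2.3,0.2,1.9,0.4,1,ref35
cochlea_height_coronal,5.58,0.26,5.31,0.52,2,ref51
cochlea_height_coronal,5.58,0.26,5.11,0.30,2,ref52
cochlea_height_oblique,3.56,0.22,3.59,0.12,2,ref53
cochlea_length,8.92,0.34,9.32,0.53,2,ref54
cochlea_length,8.92,0.34,8.84,0.29,2,ref53
cochlea_width,6.78,0.31,6.30,0.38,2,ref53
vestibule_length,5.39,0.26,5.45,0.54,2,ref55
vestibule_width,3.08,0.17,3.20,0.39,2,ref55
inner_ear_length_total,17.59,0.76,17.13,0.64,2,ref56
vol_ampulla_ant,3.54,0.43,4.20,,2,ref50
vol_ampulla_post,2.27,0.27,4.20,,2,ref50
vol_ampulla_lat,3.49,0.45,4.20,,2,ref50
vol_saccule,2.58,0.41,2.10,,2,ref50
vol_utricle,8.78,1.12,7.90,,2,ref50
vol_utricle,8.78,1.12,8.20,,2,ref57
vol_cochlea,94.42,9.41,83.80,,2,ref50
vol_inner_ear_total,269.34,24.67,221.47,24.29,2,ref56
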