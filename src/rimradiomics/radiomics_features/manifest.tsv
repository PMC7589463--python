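feature	family	applies_to
stat_mean	statistical	all
stat_variance	statistical	all
stat_skewness	statistical	all
stat_kurtosis	statistical	all
stat_median	statistical	all
stat_minimum	statistical	all
stat_p10	statistical	all
stat_p90	statistical	all
stat_maximum	statistical	all
stat_iqr	statistical	all
stat_range	statistical	all
stat_mad	statistical	all
stat_rmad	statistical	all
stat_medad	statistical	all
stat_cov	statistical	all
stat_qcod	statistical	all
stat_energy	statistical	all
stat_rms	statistical	all
ih_mean	histogram	all
ih_variance	histogram	all
ih_skewness	histogram	all
ih_kurtosis	histogram	all
ih_median	histogram	all
ih_minimum	histogram	all
ih_p10	histogram	all
ih_p90	histogram	all
ih_maximum	histogram	all
ih_mode	histogram	all
ih_iqr	histogram	all
ih_range	histogram	all
ih_mad	histogram	all
ih_rmad	histogram	all
ih_medad	histogram	all
ih_cov	histogram	all
ih_qcod	histogram	all
ih_entropy	histogram	all
ih_uniformity	histogram	all
ih_max_gradient	histogram	all
ih_max_gradient_level	histogram	all
ih_min_gradient	histogram	all
ih_min_gradient_level	histogram	all
ivh_v10	histogram	all
ivh_v25	histogram	all
ivh_v50	histogram	all
ivh_v75	histogram	all
ivh_v90	histogram	all
ivh_i10	histogram	all
ivh_i25	histogram	all
ivh_i50	histogram	all
ivh_i75	histogram	all
ivh_i90	histogram	all
ivh_diff_v10_v90	histogram	all
ivh_diff_i10_i90	histogram	all
ivh_auc	histogram	all
peak_local	histogram	all
peak_global	histogram	all
glcm_joint_max	texture	all
glcm_joint_average	texture	all
glcm_joint_variance	texture	all
glcm_joint_entropy	texture	all
glcm_diff_average	texture	all
glcm_diff_variance	texture	all
glcm_diff_entropy	texture	all
glcm_sum_average	texture	all
glcm_sum_variance	texture	all
glcm_sum_entropy	texture	all
glcm_energy	texture	all
glcm_contrast	texture	all
glcm_dissimilarity	texture	all
glcm_inv_diff	texture	all
glcm_inv_diff_norm	texture	all
glcm_inv_diff_moment	texture	all
glcm_inv_diff_moment_norm	texture	all
glcm_inv_variance	texture	all
glcm_correlation	texture	all
glcm_autocorrelation	texture	all
glcm_cluster_tendency	texture	all
glcm_cluster_shade	texture	all
glcm_cluster_prominence	texture	all
glcm_info_corr1	texture	all
glcm_info_corr2	texture	all
glrlm_sre	texture	all
glrlm_lre	texture	all
glrlm_lgre	texture	all
glrlm_hgre	texture	all
glrlm_srlge	texture	all
glrlm_srhge	texture	all
glrlm_lrlge	texture	all
glrlm_lrhge	texture	all
glrlm_glnu	texture	all
glrlm_glnu_norm	texture	all
glrlm_rlnu	texture	all
glrlm_rlnu_norm	texture	all
glrlm_run_pct	texture	all
glrlm_gl_var	texture	all
glrlm_rl_var	texture	all
glrlm_run_entropy	texture	all
glszm_sze	texture	all
glszm_lze	texture	all
glszm_lgze	texture	all
glszm_hgze	texture	all
glszm_szlge	texture	all
glszm_szhge	texture	all
glszm_lzlge	texture	all
glszm_lzhge	texture	all
glszm_glnu	texture	all
glszm_glnu_norm	texture	all
glszm_zsnu	texture	all
glszm_zsnu_norm	texture	all
glszm_zone_pct	texture	all
glszm_gl_var	texture	all
glszm_zs_var	texture	all
glszm_zs_entropy	texture	all
gldzm_sde	texture	all
gldzm_lde	texture	all
gldzm_lgze	texture	all
gldzm_hgze	texture	all
gldzm_sdlge	texture	all
gldzm_sdhge	texture	all
gldzm_ldlge	texture	all
gldzm_ldhge	texture	all
gldzm_glnu	texture	all
gldzm_glnu_norm	texture	all
gldzm_zdnu	texture	all
gldzm_zdnu_norm	texture	all
gldzm_zone_pct	texture	all
gldzm_gl_var	texture	all
gldzm_zd_var	texture	all
gldzm_zd_entropy	texture	all
ngtdm_coarseness	texture	all
ngtdm_contrast	texture	all
ngtdm_busyness	texture	all
ngtdm_complexity	texture	all
ngtdm_strength	texture	all
ngldm_lde	texture	all
ngldm_hde	texture	all
ngldm_lgce	texture	all
ngldm_hgce	texture	all
ngldm_ldlge	texture	all
ngldm_ldhge	texture	all
ngldm_hdlge	texture	all
ngldm_hdhge	texture	all
ngldm_glnu	texture	all
ngldm_glnu_norm	texture	all
ngldm_dcnu	texture	all
ngldm_dcnu_norm	texture	all
ngldm_dc_pct	texture	all
ngldm_gl_var	texture	all
ngldm_dc_var	texture	all
ngldm_dc_entropy	texture	all
ngldm_dc_energy	texture	all
morph_vol_voxel	morphology	base
morph_vol_mesh	morphology	base
morph_surface_area	morphology	base
morph_sv_ratio	morphology	base
morph_compactness1	morphology	base
morph_compactness2	morphology	base
morph_spherical_disproportion	morphology	base
morph_sphericity	morphology	base
morph_asphericity	morphology	base
morph_com_shift	morphology	base
morph_max_diameter	morphology	base
morph_major_axis	morphology	base
morph_minor_axis	morphology	base
morph_least_axis	morphology	base
morph_elongation	morphology	base
morph_flatness	morphology	base
morph_vol_density_aabb	morphology	base
morph_area_density_aabb	morphology	base
morph_vol_density_ombb	morphology	base
morph_area_density_ombb	morphology	base
morph_vol_density_aee	morphology	base
morph_area_density_aee	morphology	base
morph_vol_density_mvee	morphology	base
morph_vol_density_hull	morphology	base
morph_area_density_hull	morphology	base
morph_integrated_intensity	morphology	base
morph_moran_i	morphology	base
morph_geary_c	morphology	base
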