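# Illustrative (synthetic) breast-cancer-like variance-component table.
# One row per component x 10-year age group. deltas are case-control mean
# differences of the standardized score; familial_fraction is the share of
# delta^2 treated as familial; frr_mz is the total MZ-twin familial risk
# ratio for the age group (repeated across components). These values are
# invented for demonstration and are not estimates from any study.
component,age_group,delta,familial_fraction,r_mz,r_dz,frr_mz
major_genes,30-39,0.90,1.0,1.0,0.5,5.0
major_genes,40-49,0.70,1.0,1.0,0.5,4.0
major_genes,50-59,0.50,1.0,1.0,0.5,3.0
major_genes,60-69,0.35,1.0,1.0,0.5,2.3
major_genes,70-79,0.25,1.0,1.0,0.5,1.9
polygenic,30-39,0.35,1.0,1.0,0.5,5.0
polygenic,40-49,0.42,1.0,1.0,0.5,4.0
polygenic,50-59,0.50,1.0,1.0,0.5,3.0
polygenic,60-69,0.52,1.0,1.0,0.5,2.3
polygenic,70-79,0.52,1.0,1.0,0.5,1.9
mammogram_score,30-39,0.45,0.5,0.5,0.25,5.0
mammogram_score,40-49,0.45,0.5,0.5,0.25,4.0
mammogram_score,50-59,0.45,0.5,0.5,0.25,3.0
mammogram_score,60-69,0.45,0.5,0.5,0.25,2.3
mammogram_score,70-79,0.45,0.5,0.5,0.25,1.9
lifestyle,30-39,0.20,0.1,0.1,0.05,5.0
lifestyle,40-49,0.25,0.1,0.1,0.05,4.0
lifestyle,50-59,0.30,0.1,0.1,0.05,3.0
lifestyle,60-69,0.35,0.1,0.1,0.05,2.3
lifestyle,70-79,0.40,0.1,0.1,0.05,1.9
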