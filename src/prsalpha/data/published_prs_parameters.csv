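prs,n_snps,mean_controls,mean_cases,sd_controls,sd_cases,log_or_per_sd,log_or_ci_low,log_or_ci_high,alpha_glm,alpha_rl,alpha_rl_ci_low,alpha_rl_ci_high,predicted_alpha_rl
BCAC_PRS313,313,-0.424,-0.114,0.611,0.619,0.497,0.476,0.519,0.397,0.441,0.430,0.455,0.441
BRIDGES,306,-0.422,-0.114,0.608,0.615,0.495,0.474,0.517,0.394,0.439,0.425,0.450,0.439
PERSPECTIVE,295,-0.448,-0.147,0.599,0.609,0.489,0.468,0.511,0.389,0.433,0.420,0.450,0.434
EASTGLH,303,-0.407,-0.100,0.606,0.613,0.494,0.472,0.516,0.394,0.438,0.420,0.450,0.438
PRISMA,268,0.322,0.575,0.558,0.565,0.446,0.424,0.467,0.358,0.396,0.385,0.410,0.395
eMERGE,308,-0.456,-0.150,0.608,0.616,0.495,0.473,0.516,0.394,0.439,0.425,0.450,0.439
DBDS299,299,-0.508,-0.211,0.596,0.605,0.486,0.465,0.508,0.387,0.432,0.440,0.455,0.431
BCAC_PRS77,77,-0.892,-0.703,0.449,0.460,0.394,0.373,0.415,0.310,0.350,0.340,0.360,0.349
BCAC_PRS3820,3820,-0.445,-0.199,0.460,0.463,0.518,0.496,0.540,0.412,0.454,0.440,0.470,0.459
WISDOM75,74,-1.057,-0.835,0.567,0.573,0.360,0.338,0.381,0.281,0.315,0.300,0.330,0.319
WISDOM128,126,-0.180,0.041,0.464,0.478,0.449,0.427,0.470,0.355,0.402,0.390,0.415,0.398
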