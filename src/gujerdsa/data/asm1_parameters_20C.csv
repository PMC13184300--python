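name,value,unit,description
# ASM1 default parameter set at 20 degC (original activated-sludge model
# report, typical values); K_NH_H and i_COD_NO3 belong to the
# mass-balance-corrected variant (ammonia nutrient limitation of
# heterotrophic growth; COD conversion factor of nitrate).
Y_H,0.67,g COD (g COD)-1,heterotrophic yield (gamma_h)
Y_A,0.24,g COD (g N)-1,autotrophic yield (gamma_a)
f_P,0.08,-,fraction of biomass becoming particulate products
i_XB,0.086,g N (g COD)-1,nitrogen content of biomass
i_XP,0.06,g N (g COD)-1,nitrogen content of particulate products
mu_H,6.0,d-1,maximum heterotrophic growth rate (mu_max_h)
K_S,20.0,g COD m-3,half-saturation for readily biodegradable substrate (kappa_b)
K_OH,0.20,g O2 m-3,oxygen half-saturation for heterotrophs (kappa_O2_h)
K_NO,0.50,g N m-3,nitrate half-saturation for denitrifying heterotrophs
b_H,0.62,d-1,heterotrophic decay rate
eta_g,0.8,-,anoxic growth correction factor
eta_h,0.4,-,anoxic hydrolysis correction factor
k_h,3.0,g COD (g COD d)-1,maximum specific hydrolysis rate
K_X,0.03,g COD (g COD)-1,half-saturation for hydrolysis of slowly biodegradable substrate
mu_A,0.8,d-1,maximum autotrophic growth rate (mu_max_a)
K_NH,1.0,g N m-3,ammonia half-saturation for autotrophs (kappa_NHx_a)
K_OA,0.4,g O2 m-3,oxygen half-saturation for autotrophs (kappa_O2_a)
b_A,0.05,d-1,autotrophic decay rate
k_a,0.08,m3 (g COD d)-1,ammonification rate constant
K_NH_H,0.05,g N m-3,ammonia half-saturation for heterotrophic growth (kappa_NHx_h)
i_COD_NO3,-4.5714285714285714,g COD (g N)-1,COD conversion factor of nitrate (-64/14)
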