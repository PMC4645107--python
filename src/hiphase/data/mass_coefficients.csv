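# Mass attenuation (mu/rho) and mass energy-absorption (mu_en/rho)
# coefficients, cm^2/g, on a coarse energy grid around 8.48 keV.
# Si attenuation values follow standard tabulations (rounded); the
# protein energy-absorption values are a reduced estimate for a generic
# protein-crystal medium (photoabsorption-dominated, ~E^-3 scaling) and
# are labelled an estimate: absolute doses derived from them depend on
# the averaging convention.  Interpolation is log-log.
material,kind,density_g_cm3,energy_keV,mu_rho_cm2_g
Si,attenuation,2.33,6.0,147.0
Si,attenuation,2.33,8.0,64.7
Si,attenuation,2.33,10.0,33.9
Si,attenuation,2.33,12.0,20.0
protein,energy_absorption,1.35,6.0,12.99
protein,energy_absorption,1.35,8.0,5.48
protein,energy_absorption,1.35,10.0,2.81
protein,energy_absorption,1.35,12.0,1.62
water,energy_absorption,1.00,6.0,12.24
water,energy_absorption,1.00,8.0,5.19
water,energy_absorption,1.00,10.0,2.68
water,energy_absorption,1.00,12.0,1.54
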