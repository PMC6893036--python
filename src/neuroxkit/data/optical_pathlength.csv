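# Hemoglobin molar extinction coefficients (1/(cm*M), standard tabulated
# values) and Monte Carlo style differential pathlength factors (cm) per
# illumination wavelength. Editable configuration, not code constants.
wavelength_nm,eps_hbo,eps_hbr,pathlength_cm
470,33209.2,16156.4,0.048
530,39956.8,39036.4,0.057
660,319.6,3226.56,0.250
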