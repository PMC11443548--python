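# Bio-optical and fluorescence coefficients used by seabloom.mixedlayer and
# seabloom.fluorescence. Kept as configuration so coefficient updates from the
# source literature never touch code.

kd490:
  # Diffuse attenuation at 490 nm from surface chlorophyll:
  # Kd(490) = kw + a * Chl^e   (Morel et al. 2007, ocean-colour consistency
  # of Kd products; kw is the pure-water contribution at 490 nm, m^-1)
  kw: 0.0166
  a: 0.0773
  e: 0.6715

kdpar:
  # Broadband attenuation over the first penetration depths from Kd(490):
  # Kd(PAR) = c0 + c1 * Kd490 + c2 / Kd490   (Morel et al. 2007)
  c0: 0.0665
  c1: 0.874
  c2: -0.00121

phif:
  # Chlorophyll fluorescence quantum yield: fluorescence emission inferred
  # from nFLH divided by the radiation absorbed by phytoplankton, with the
  # chlorophyll-specific absorption given as a Bricaud-style power law
  # a_ph = absorption_a * Chl^absorption_e (m^-1) and a single radiometric
  # factor collecting the band-to-broadband, steradian and quanta
  # conversions of the satellite fluorescence retrieval
  # (Behrenfeld et al. 2009 formulation).
  fluorescence_scale: 5000.0
  absorption_a: 0.0654
  absorption_e: 0.728
  chl_floor: 0.01      # mg m-3; below this the retrieval is not credible
  ipar_floor: 1.0      # uEin m-2 s-1
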