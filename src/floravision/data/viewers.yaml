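# Default viewer phenotypes.
#
# Receptor sensitivities are generated at run time from an A1 visual-pigment
# nomogram at the lambda_max values below; edit this file (or pass overrides
# to build_viewer) to change a phenotype without touching code.
#
# bee: honeybee (Apis mellifera) trichromat; hexagon color space with the
#   behaviorally validated discrimination threshold of 0.11 hexagon units.
# bird_VS / bird_UVS: average violet-sensitive and ultraviolet-sensitive
#   avian tetrachromats as conventionally parameterized in the visual-ecology
#   literature; receptor-noise-limited space, threshold 1 JND, Weber fraction
#   0.1 for the most abundant (long-wavelength) cone class, relative cone
#   densities 1:2:2:4 (uv/violet : short : medium : long).

bee:
  model: hexagon
  threshold: 0.11
  receptor_names: [uv, blue, green]
  lambda_max: [344.0, 436.0, 544.0]

bird_VS:
  model: rnl
  threshold: 1.0
  weber_fraction: 0.1
  receptor_names: [v, s, m, l]
  lambda_max: [416.0, 478.0, 542.0, 607.0]
  relative_densities: [1.0, 2.0, 2.0, 4.0]

bird_UVS:
  model: rnl
  threshold: 1.0
  weber_fraction: 0.1
  receptor_names: [uv, s, m, l]
  lambda_max: [372.0, 456.0, 544.0, 609.0]
  relative_densities: [1.0, 2.0, 2.0, 4.0]
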