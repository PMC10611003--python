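# Two sets of epoxy/TiO2/Nigrosin slab phantoms characterized at 633 nm.
# Uncertainties (sd_* keys) are standard deviations of three measurements
# at different sample positions.  The anisotropy factor g of the embedded
# scatterers is not part of the characterization output and must be chosen
# explicitly; the package default (0.6) is applied on load.
phantoms:
  - id: "1.1"
    d_mm: 0.395
    sd_d_mm: 0.009
    mus_prime_per_mm: 3.688
    sd_mus_prime_per_mm: 0.005
    mua_per_mm: 0.0034
    sd_mua_per_mm: 0.0003
  - id: "1.2"
    d_mm: 0.947
    sd_d_mm: 0.004
    mus_prime_per_mm: 3.781
    sd_mus_prime_per_mm: 0.002
    mua_per_mm: 0.0020
    sd_mua_per_mm: 0.0001
  - id: "1.3"
    d_mm: 1.514
    sd_d_mm: 0.009
    mus_prime_per_mm: 3.841
    sd_mus_prime_per_mm: 0.004
    mua_per_mm: 0.0020
    sd_mua_per_mm: 0.0001
  - id: "1.4"
    d_mm: 1.987
    sd_d_mm: 0.003
    mus_prime_per_mm: 3.817
    sd_mus_prime_per_mm: 0.005
    mua_per_mm: 0.0019
    sd_mua_per_mm: 0.0001
  - id: "2.1"
    d_mm: 0.901
    sd_d_mm: 0.008
    mus_prime_per_mm: 2.724
    sd_mus_prime_per_mm: 0.003
    mua_per_mm: 0.0213
    sd_mua_per_mm: 0.0001
  - id: "2.2"
    d_mm: 1.045
    sd_d_mm: 0.003
    mus_prime_per_mm: 2.757
    sd_mus_prime_per_mm: 0.001
    mua_per_mm: 0.0598
    sd_mua_per_mm: 0.0001
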