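# Material library for theoretical HU / DEI prediction.
# Densities are standard elemental values in g/cm3; ballistic gelatine is
# modelled as water (tissue surrogate, density 1.0).
materials:
  water:
    name: water
    symbol: H2O
    atomic_number: null
    density_g_cm3: 1.00
    table: water.tsv
  iron:
    name: iron
    symbol: Fe
    atomic_number: 26
    density_g_cm3: 7.87
    table: iron.tsv
  copper:
    name: copper
    symbol: Cu
    atomic_number: 29
    density_g_cm3: 8.96
    table: copper.tsv
  tungsten:
    name: tungsten
    symbol: W
    atomic_number: 74
    density_g_cm3: 19.30
    table: tungsten.tsv
  lead:
    name: lead
    symbol: Pb
    atomic_number: 82
    density_g_cm3: 11.35
    table: lead.tsv
  bismuth:
    name: bismuth
    symbol: Bi
    atomic_number: 83
    density_g_cm3: 9.78
    table: bismuth.tsv
aliases:
  fe: iron
  steel: iron      # "steel" shotgun pellets are soft iron
  cu: copper
  w: tungsten
  pb: lead
  bi: bismuth
  h2o: water
  gelatine: water
  gelatin: water
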