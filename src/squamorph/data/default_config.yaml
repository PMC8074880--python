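# Default chronostratigraphic and vocabulary configuration.
#
# Numeric stage ages (Ma) follow the ICS International Chronostratigraphic
# Chart (2020 edition). Users may supply their own stage table CSV to
# override these; nothing downstream assumes this particular timescale.
stages:
  - {name: Kimmeridgian,  base_age: 157.3, top_age: 152.1}
  - {name: Tithonian,     base_age: 152.1, top_age: 145.0}
  - {name: Berriasian,    base_age: 145.0, top_age: 139.8}
  - {name: Valanginian,   base_age: 139.8, top_age: 132.9}
  - {name: Hauterivian,   base_age: 132.9, top_age: 129.4}
  - {name: Barremian,     base_age: 129.4, top_age: 125.0}
  - {name: Aptian,        base_age: 125.0, top_age: 113.0}
  - {name: Albian,        base_age: 113.0, top_age: 100.5}
  - {name: Cenomanian,    base_age: 100.5, top_age: 93.9}
  - {name: Turonian,      base_age: 93.9,  top_age: 89.8}
  - {name: Coniacian,     base_age: 89.8,  top_age: 86.3}
  - {name: Santonian,     base_age: 86.3,  top_age: 83.6}
  - {name: Campanian,     base_age: 83.6,  top_age: 72.1}
  - {name: Maastrichtian, base_age: 72.1,  top_age: 66.0}

# Epoch-level bins (standard chronostratigraphy).
epoch_bins:
  - label: Late Jurassic
    member_stages: [Kimmeridgian, Tithonian]
  - label: Early Cretaceous
    member_stages: [Berriasian, Valanginian, Hauterivian, Barremian, Aptian, Albian]
  - label: Late Cretaceous
    member_stages: [Cenomanian, Turonian, Coniacian, Santonian, Campanian, Maastrichtian]

# Multi-stage bins used for the jaw-size disparity contrasts.
size_test_bins:
  - label: Aptian-Albian
    member_stages: [Aptian, Albian]
  - label: Cenomanian-Turonian
    member_stages: [Cenomanian, Turonian]
  - label: Campanian
    member_stages: [Campanian]

# Dental morphotype vocabulary: eight discrete tooth-shape categories used as
# dietary proxies. The eighth category is deliberately configurable.
morphotypes:
  - conical
  - compressed-pointed-recurved
  - hooked-slender
  - bicuspid
  - tricuspid
  - polycuspid-leaf-shaped
  - crushing
  - other-specialised

habitats: [terrestrial, marine]
clades: [lizard, snake, mosasauroid, dolichosaur, amphisbaenian]
diets: [carnivore, insectivore, herbivore, durophage, piscivore]
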