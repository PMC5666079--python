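# Order/clade -> five-group mapping for the stratified mammalian analysis.
# Groups: Rodentia (Glires incl. rabbits), Cetacea, Primates,
# Laurasiatheria (excluding cetaceans), others (Afrotheria, Xenarthra,
# Marsupialia, ...).  Users with species-level assignments should supply
# their own grouping CSV instead.
Rodentia: Rodentia
Lagomorpha: Rodentia
Cetacea: Cetacea
Primates: Primates
Carnivora: Laurasiatheria
Artiodactyla: Laurasiatheria
Cetartiodactyla: Laurasiatheria
Perissodactyla: Laurasiatheria
Chiroptera: Laurasiatheria
Eulipotyphla: Laurasiatheria
Soricomorpha: Laurasiatheria
Erinaceomorpha: Laurasiatheria
Pholidota: Laurasiatheria
Proboscidea: others
Sirenia: others
Hyracoidea: others
Afrosoricida: others
Macroscelidea: others
Tubulidentata: others
Cingulata: others
Pilosa: others
Didelphimorphia: others
Diprotodontia: others
Dasyuromorphia: others
Peramelemorphia: others
Monotremata: others
Scandentia: others
Dermoptera: others
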