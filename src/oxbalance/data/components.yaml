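# Default oxidative-balance-score roster: 22 components (17 dietary, 5 lifestyle).
# polarity: antioxidant components score 0/1/2 with increasing intake,
# prooxidant components score 2/1/0. rule: tertile = sex-stratified tertile
# cut-points; abstention_binary = non-consumers score 2, consumers split at
# the consumer median (lower half 1, upper half 0).
components:
  # dietary pro-oxidants
  - {name: total_fat, category: dietary, polarity: prooxidant, rule: tertile, source_columns: [total_fat]}
  - {name: iron, category: dietary, polarity: prooxidant, rule: tertile, source_columns: [iron]}
  - {name: pufa, category: dietary, polarity: prooxidant, rule: tertile, source_columns: [pufa]}
  - {name: sfa, category: dietary, polarity: prooxidant, rule: tertile, source_columns: [sfa]}
  - {name: meat, category: dietary, polarity: prooxidant, rule: abstention_binary,
     source_columns: [beef, lamb, pork], combine: sum}
  # dietary antioxidants
  - {name: calcium, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [calcium]}
  - {name: magnesium, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [magnesium]}
  - {name: vitamin_b6, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [vitamin_b6]}
  - {name: vitamin_b12, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [vitamin_b12]}
  - {name: vitamin_c, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [vitamin_c]}
  - {name: vitamin_d, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [vitamin_d]}
  - {name: vitamin_e, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [vitamin_e]}
  - {name: total_folate, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [total_folate]}
  - {name: carotenoids, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [carotenoids]}
  - {name: fiber, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [fiber]}
  - {name: retinol, category: dietary, polarity: antioxidant, rule: tertile, source_columns: [retinol]}
  - {name: vegetable, category: dietary, polarity: antioxidant, rule: tertile,
     source_columns: [raw_vegetables, cooked_vegetables], combine: sum}
  # lifestyle pro-oxidants
  - {name: smoking, category: lifestyle, polarity: prooxidant, rule: abstention_binary, source_columns: [smoking]}
  - {name: alcohol, category: lifestyle, polarity: prooxidant, rule: abstention_binary, source_columns: [alcohol]}
  - {name: bmi, category: lifestyle, polarity: prooxidant, rule: tertile, source_columns: [bmi]}
  # lifestyle antioxidants
  - {name: tea, category: lifestyle, polarity: antioxidant, rule: tertile, source_columns: [tea]}
  - {name: physical_activity, category: lifestyle, polarity: antioxidant, rule: tertile,
     source_columns: [met_light, met_moderate, met_vigorous], combine: sum}
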