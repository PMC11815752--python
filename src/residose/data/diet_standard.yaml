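# Standard one-day diet of animal-origin foods for a 60 kg adult, anchored to
# the EFSA protein PRI (0.83 g/kg bw/day).  One portion of milk, one egg
# (53 g, CREA portion unit), one portion of meat (chicken breast) and one of
# fish (cod).
consumer_bw_kg: 60
pri_g_per_kg: 0.83
portions:
  - food_id: milk
    mass_g: 200
  - food_id: egg
    mass_g: 53
  - food_id: chicken_breast
    mass_g: 100
  - food_id: cod
    mass_g: 100
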