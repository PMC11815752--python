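food_id	label	matrix	protein_per_100g
milk	Pasteurized cow's milk, semi-skimmed	milk	3.5
egg	Hen egg, whole	eggs	12.4
chicken_breast	Chicken breast, raw	muscle	23.3
cod	Cod or hake, raw	muscle	17
beef_loin	Adult bovine loin, trimmed of visible fat	muscle	21.8
pork_loin	Pork loin, raw	muscle	20.7
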