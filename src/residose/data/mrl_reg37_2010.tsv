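substance	class	matrix	limit_ug_per_kg	provisions
chlortetracycline	tetracycline	muscle	100	fin_fish_muscle_skin
chlortetracycline	tetracycline	liver	300	mrl_not_for_fin_fish
chlortetracycline	tetracycline	kidney	600	mrl_not_for_fin_fish
chlortetracycline	tetracycline	milk	100
chlortetracycline	tetracycline	eggs	200
sulfonamides	sulfonamide	muscle	100	class_combined_total;fin_fish_muscle_skin;not_for_egg_producers
sulfonamides	sulfonamide	fat	100	class_combined_total;mrl_not_for_fin_fish;not_for_egg_producers
sulfonamides	sulfonamide	liver	100	class_combined_total;mrl_not_for_fin_fish;not_for_egg_producers
sulfonamides	sulfonamide	kidney	100	class_combined_total;mrl_not_for_fin_fish;not_for_egg_producers
sulfonamides	sulfonamide	milk	100	class_combined_total;not_for_egg_producers
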