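experiment_id,vent_field,site,fluid_id,sample_name,habitat,approach,temperature_C,euk_cells_ml,euk_min,euk_max,prok_cells_ml,prok_min,prok_max,hourly_uptake_printed,grazing_rate_printed,clearance_printed,specific_grazing_printed,turnover_printed,status
vd-background-ctd002,VonDamm,Background,CTD002,Niskins 8-10,background,ambient,4.2,91.838,69.97,113.7,3.79e4,1.85e4,5.65e4,0.178,127.07,3.70e-5,1.38,8.0,detected
vd-plume-ctd001,VonDamm,Plume,CTD001,Niskin 2,plume,ambient,4.2,157.77,55.98,284.4,1.65e4,1.39e4,1.91e4,0.316,24.03,9.24e-6,0.15,3.5,detected
vd-mustardstand-lv17,VonDamm,Mustard Stand,J2-1243,LV17,vent,ambient,108.0,259.77,230.9,288.6,5.67e4,4.24e4,7.10e4,,,,,,bd
vd-oldmantree-igt4,VonDamm,Old Man Tree,J2-1238,IGT4,vent,igt,121.6,349.86,,,UNCOUNTABLE,,,0.226,1050.38,4.22e-5,3.00,35.0,detected
vd-ravelin2-lv13a,VonDamm,Ravelin #2,J2-1238,LV13a,vent,ambient,94.0,409.33,335.9,482.8,UNCOUNTABLE,,,0.208,116.86,4.01e-6,0.29,3.9,detected
vd-ravelin2-igt4,VonDamm,Ravelin #2,J2-1244,IGT4,vent,igt,98.2,944.62,,,UNCOUNTABLE,,,1.264,15867.10,2.40e-4,16.80,540.0,detected
vd-ravelin2-igt5,VonDamm,Ravelin #2,J2-1244,IGT5,vent,igt,98.2,629.74,,,UNCOUNTABLE,,,,,,,,bd
vd-shrimphole-lv13,VonDamm,Shrimp Hole,J2-1244,LV13,vent,ambient,21.0,385.72,377.8,393.6,4.20e4,3.88e4,4.51e4,,,,,,bd
vd-x18-lv23,VonDamm,X-18,J2-1235,LV23 & Bio5,vent,ambient,48.0,314.87,209.9,419.8,1.11e5,1.09e5,1.14e5,0.105,1166.28,3.32e-5,3.70,25.0,detected
pc-plume-ctd004,Piccard,Plume,CTD004,Niskin 10,plume,ambient,4.5,79.301,55.98,112,5.14e4,4.68e4,5.61e4,0.322,44.26,1.10e-5,0.56,2.1,detected
pc-lotsoshrimp-lv24,Piccard,Lots 'O Shrimp,J2-1241,LV24,vent,ambient,36.0,230.91,230.9,230.9,5.39e4,2.62e4,9.03e4,,,,,,bd
pc-shrimpocalypse-lv13,Piccard,Shrimpocalypse,J2-1240,LV13,vent,ambient,85.0,454.82,,,2.39e5,1.090e5,3.22e5,0.941,6006.91,5.54e-5,13.21,60.0,detected
pc-shrimpocalypse-igt3,Piccard,Shrimpocalypse,J2-1240,IGT3,vent,igt,85.0,384.84,,,2.39e5,1.090e5,3.22e5,1.008,17284.68,1.90e-4,44.91,170.0,detected
pc-shrimpocalypse-igt7,Piccard,Shrimpocalypse,J2-1240,IGT7,vent,igt,85.0,524.79,,,2.39e5,1.090e5,3.22e5,,,,,,na
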