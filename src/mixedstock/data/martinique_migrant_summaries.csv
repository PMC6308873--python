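track_id,n_loc,duration_days,distance_km,speed_mean_kmh,speed_sd_kmh,ccl_cm,body_mass_kg
150122,306,291,5094,1.4,1.2,82,66.4
149691,142,51,2649,1.7,1.6,81,67.4
149692,259,184,4213,1.4,1.3,86,80.4
149693,171,134,2645,1.1,1.4,83,71.5
149694,364,78,3098,2.2,1.4,84,75.4
149696,429,200,7821,2.2,1.2,88,81.4
149697,567,288,1370,0.6,0.9,78.5,61.6
164547,845,145,5844,2.1,1.2,88,73.8
164548,886,148,6104,2.0,1.3,88.5,77.6
45811,1186,135,5108,1.9,1.2,93,91.6
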