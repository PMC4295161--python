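differentiation_time.diff_spg: 205
differentiation_time.leptotene: 30
differentiation_time.pachytene: 168
differentiation_time.preleptotene: 44
differentiation_time.round_sptd: 138
differentiation_time.zygotene: 38
division_time.diff_spg: 88
division_time.diplotene: 26
division_time.secondary: 12
division_time.stem: 190
geometry.compartment_um: 13.0
geometry.interstitial_count: 5
geometry.lumen_radius: 4
geometry.sertoli_count: 10
geometry.tubule_radius: 14
initial_counts.diff_spg: 20
initial_counts.elongated_sptd: 90
initial_counts.pachytene: 30
initial_counts.round_sptd: 100
initial_counts.stem: 10
initial_stem_count: 10
lifespan_max.diff_spg: 280
lifespan_max.diplotene: 64
lifespan_max.elongated_sptd: 300
lifespan_max.leptotene: 68
lifespan_max.pachytene: 340
lifespan_max.preleptotene: 82
lifespan_max.round_sptd: 250
lifespan_max.secondary: 31
lifespan_max.zygotene: 76
lifespan_min.diff_spg: 190
lifespan_min.diplotene: 23
lifespan_min.elongated_sptd: 200
lifespan_min.leptotene: 27
lifespan_min.pachytene: 155
lifespan_min.preleptotene: 41
lifespan_min.round_sptd: 128
lifespan_min.secondary: 11
lifespan_min.zygotene: 35
position_domain.diff_spg:
- 13.0
- 14.0
position_domain.diplotene:
- 8.0
- 12.0
position_domain.elongated_sptd:
- 4.0
- 6.0
position_domain.leptotene:
- 10.0
- 13.0
position_domain.pachytene:
- 8.0
- 12.0
position_domain.preleptotene:
- 12.0
- 14.0
position_domain.round_sptd:
- 5.0
- 9.0
position_domain.secondary:
- 8.0
- 12.0
position_domain.stem:
- 13.0
- 14.0
position_domain.zygotene:
- 10.0
- 13.0
preleptotene_threshold: 5
release_delay: 196
spg_mitosis_rounds: 3
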