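acid_base_min: 3.0
circular: false
de_fraction_hi: 0.23863636363636365
de_fraction_lo: 0.15178571428571427
esi_filter_enabled: true
esi_mode: strict_natural
extra_patterns: []
gc_bin_width: 5.0
gc_priority_range:
- 25.0
- 35.0
glypro_filter_enabled: true
glypro_hi: 0.08333333333333333
glypro_lo: 0.022727272727272728
gravy_hi: 0.29017857142857145
gravy_lo: -0.49734513274336284
length_check: post_trim
mass_hi: 12632.8028
mass_lo: 9475.6186
max_len: 113
min_len: 84
orf_min_len: 40
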