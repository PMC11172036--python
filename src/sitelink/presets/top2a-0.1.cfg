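# Chordate Top2A alignment run: 105 sequences, human Top2A as reference row.
# 56% non-insertion keeps the column count at the reference length (1531);
# 0.1 nats removes sites that vary at most once across the alignment.
format = csv
first_row_mapping = true
non_insertion_pct = 56
entropy_threshold = 0.1
spread = 1
max_order = 10
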