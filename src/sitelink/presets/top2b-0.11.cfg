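# Chordate Top2B alignment run: 125 sequences, human Top2B as reference row.
# 14% non-insertion keeps the column count at the reference length (1626);
# 0.11 nats also removes sites that vary twice across the alignment.
format = csv
first_row_mapping = true
non_insertion_pct = 14
entropy_threshold = 0.11
spread = 1
max_order = 10
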