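# Region annotations for human topoisomerase IIα (P11388), 1-based inclusive.
# Editable configuration: name, start, end, notes
CTD, 1175, 1531, intrinsically disordered C-terminal domain
NLS, 1259, 1296, nuclear localization sequence
NLS, 1454, 1497, nuclear localization sequence
SUMO, 1228, 1228, sumoylation site K1228
PO4, 1295, 1295, phosphorylation site S1295; mitosis-associated (Plk-1)
PO4, 1332, 1332, phosphorylation site S1332; mitosis-associated (Plk-1)
PO4, 1525, 1525, phosphorylation site S1525; decatenation checkpoint
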