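# Default editing (proofreading) table: ligands against which each aaRS
# performs pre- or post-transfer correction.  Approximate: restricted to the
# 22-code ligand vocabulary, so non-proteinogenic editing targets (e.g.
# norvaline for LeuRS, homocysteine for MetRS) cannot be represented and the
# corresponding entries are reduced or empty.  Override with your own file
# for curated analyses.
IleRS: [Val]
ValRS: [Thr]
LeuRS: [Ile, Met]
MetRS: []          # natural target homocysteine is outside the vocabulary
AlaRS: [Gly, Ser]
ThrRS: [Ser]
ProRS: [Ala, Cys]
PheRS: [Tyr, Ile]
SerRS: [Thr]
LysRS: []
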