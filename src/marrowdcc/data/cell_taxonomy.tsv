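name	countable
apoptotic cell	0
atypical lymphocyte	0
band neutrophil	1
basophil	1
early erythroblast	1
eosinophil	1
immature lymphocyte	0
immature monocyte	1
intermediate erythroblast	1
intermediate neutrophilic myelocyte	1
late erythroblast	1
late neutrophilic myelocyte	1
lymphocyte	1
monocyte	1
myeloblast	1
plasma cell	1
prolymphocyte	0
promonocyte	1
promyelocyte	1
segmented neutrophil	1
smudge cell	0
others	0
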