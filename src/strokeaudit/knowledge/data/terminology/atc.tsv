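-- ATC subset for the acute-stroke content (reconstructed, non-normative).
-- Anticoagulants are detected as the B01A subtree.
code	display	parents
B01	Antithrombotic agents
B01A	Antithrombotic agents	B01
B01AA	Vitamin K antagonists	B01A
B01AA03	Warfarin	B01AA
B01AB	Heparin group	B01A
B01AB01	Heparin	B01AB
N02	Analgesics
N02BE01	Paracetamol	N02
C07	Beta blocking agents
C07AB07	Bisoprolol	C07
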