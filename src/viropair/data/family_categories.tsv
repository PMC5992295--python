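family	category
Siphoviridae	phage
Myoviridae	phage
Podoviridae	phage
Microviridae	phage
Inoviridae	phage
Ackermannviridae	phage
Herelleviridae	phage
Corticoviridae	phage
Tectiviridae	phage
Leviviridae	phage
Herpesviridae	eukaryotic
Phycodnaviridae	eukaryotic
Anelloviridae	eukaryotic
Papillomaviridae	eukaryotic
Polyomaviridae	eukaryotic
Adenoviridae	eukaryotic
Parvoviridae	eukaryotic
Picornaviridae	eukaryotic
Poxviridae	eukaryotic
Mimiviridae	eukaryotic
Circoviridae	eukaryotic
Retroviridae	eukaryotic
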