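id	name	formula	n_carboxyl	n_ketone	n_aldehyde	notes
kinetin	kinetin	C10H9N5O	0	0	0	plant hormone; no derivatizable carbonyl (amide/aromatic O only)
succinyl_proline	succinyl proline	C9H13NO5	2	0	0	free succinyl carboxyl + proline carboxyl; amide carbonyls not reactive
glutamate	glutamate	C5H9NO4	2	0	0	alpha + side-chain carboxyl
methionine	methionine	C5H11NO2S	1	0	0	single carboxyl; thioether S
butanoate	butanoic acid	C4H8O2	1	0	0	short-chain fatty acid
acetoin	acetoin	C4H8O2	0	1	0	3-hydroxy-2-butanone; isomer of butanoate
malate	malate	C4H6O5	2	0	0	dicarboxylic acid, no keto group
dehydrothreonate	dehydrothreonate	C4H6O5	1	1	0	oxocarboxylic acid; isomer of malate
citrate	citrate	C6H8O7	3	0	0	tricarboxylic acid
homocitrate	homocitrate	C7H10O7	3	0	0	tricarboxylic acid
pyruvate	pyruvic acid	C3H4O3	1	1	0	oxocarboxylic acid with a ketone
glyoxalate	glyoxalic acid	C2H2O3	1	0	1	oxocarboxylic acid with an aldehyde
hydroxyacetone	hydroxyacetone	C3H6O2	0	1	0	demethylated analog of acetoin
pentanoate	pentanoic acid	C5H10O2	1	0	0	short-chain fatty acid
hexosamine	hexosamine	C6H13NO5	0	0	1	reducing sugar; open-chain aldehyde assumed (interpretation)
glcnac	N-acetylhexosamine (GlcNAc)	C8H15NO6	0	0	1	reducing sugar; open-chain aldehyde assumed (interpretation)
ffa_c14	tetradecanoic acid	C14H28O2	1	0	0	medium-chain free fatty acid
ffa_c16	hexadecanoic acid	C16H32O2	1	0	0	medium-chain free fatty acid
ffa_c18	octadecanoic acid	C18H36O2	1	0	0	long-chain free fatty acid
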