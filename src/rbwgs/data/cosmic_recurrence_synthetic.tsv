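gene	variant_key	count
RB1	13:48941648:C:T	12
RB1	13:48953740:C:T	7
CREBBP	16:3788617:G:A	5
MDM4	1:204501319:A:G	3
BCOR	X:39921444:G:T	2
EXT2	11:44180000:G:T	1
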