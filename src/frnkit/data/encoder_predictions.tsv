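# Predicted direction of each pairwise condition contrast (row) under each
# encoder (column).  Cells: ">" first more positive, "<" second more
# positive, "=" no difference.  RPE+ = RPE coded by voltage positivity
# (the conventional FRN direction); SAL+ = physical salience coded by
# voltage positivity; NULL = neither property encoded.
contrast	RPE+	RPE-	SAL+	SAL-	NULL
HN/HP	<	>	>	<	=
HN/LN	=	=	>	<	=
HN/LP	<	>	>	<	=
HP/LN	>	<	=	=	=
HP/LP	=	=	>	<	=
LN/LP	<	>	>	<	=
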