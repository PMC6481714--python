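# Exemplar conditional stacking-propensity table for the NAC beta-helix
# register ("published units", directional lower->upper).
# provenance column:
#   exemplar          - value as published for BETAWRAP-derived beta-helix
#                       conditional alignment probabilities
#   derived_ratio     - back-constructed so that published propensity RATIOS
#                       hold (Q50/H50 vs N65 = 2; D51/G51 vs K = 6); the
#                       absolute values are not published
#   synthetic_neutral - filler for register pairs with no published value,
#                       chosen equal for wildtype and mutant letters so they
#                       contribute factor 1 to designed fold-changes
aa_lower	aa_upper	burial	score	provenance
L	K	exposed	28	exemplar
L	K	buried	7	exemplar
V	V	buried	25.4	exemplar
I	R	buried	5.8	exemplar
K	A	exposed	5.8	exemplar
P	A	exposed	0.7	exemplar
H	N	buried	4.0	derived_ratio
Q	N	buried	8.0	derived_ratio
K	G	exposed	2.0	derived_ratio
K	D	exposed	12.0	derived_ratio
G	K	exposed	2.0	derived_ratio
D	K	exposed	12.0	derived_ratio
K	K	exposed	10.0	synthetic_neutral
D	P	exposed	10.0	synthetic_neutral
V	T	buried	9.0	synthetic_neutral
R	T	buried	9.0	synthetic_neutral
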