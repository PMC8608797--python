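# BRAFV600E-MEK-ERK cascade reaction inventory (R.1-R.36).
# One row per numbered reaction; `binding` rows are reversible (fwd_rate/rev_rate),
# `catalysis` rows are irreversible (fwd_rate only). The dot (·) marks complexes.
# drug_tag: dbf rows carry dabrafenib (*), tmt rows carry trametinib (**); both
# sets can be dropped when simulating without the corresponding inhibitor.
# Ordering convention inside complex names: enzyme · ATP · drug · substrate.
id	kind	reactants	products	fwd_rate	rev_rate	drug_tag
R.1	binding	BRAF + ATP	BRAF·ATP	a1	d1	none
R.2	binding	BRAF·ATP + MEK	BRAF·ATP·MEK	a2	d2	none
R.3	catalysis	BRAF·ATP·MEK	BRAF + ADP + pMEK	k12		none
R.4	binding	BRAF·ATP + pMEK	BRAF·ATP·pMEK	a2	d2	none
R.5	catalysis	BRAF·ATP·pMEK	BRAF + ADP + ppMEK	k12		none
R.6	binding	BRAF + MEK	BRAF·MEK	a2	d2	none
R.7	binding	BRAF + pMEK	BRAF·pMEK	a2	d2	none
R.8	binding	phosph1 + pMEK	phosph1·pMEK	a3	d3	none
R.9	catalysis	phosph1·pMEK	phosph1 + MEK	k3		none
R.10	binding	phosph1 + ppMEK	phosph1·ppMEK	a3	d3	none
R.11	catalysis	phosph1·ppMEK	phosph1 + pMEK	k3		none
R.12	binding	BRAF + DBF	BRAF·DBF	a4	d4	dbf
R.13	binding	BRAF·DBF + MEK	BRAF·DBF·MEK	a2	d2	dbf
R.14	binding	BRAF·DBF + pMEK	BRAF·DBF·pMEK	a2	d2	dbf
R.15	binding	ppMEK + ATP	ppMEK·ATP	a5	d5	none
R.16	binding	ppMEK·ATP + ERK	ppMEK·ATP·ERK	a6	d6	none
R.17	catalysis	ppMEK·ATP·ERK	ppMEK + ADP + pERK	k56		none
R.18	binding	ppMEK·ATP + pERK	ppMEK·ATP·pERK	a6	d6	none
R.19	catalysis	ppMEK·ATP·pERK	ppMEK + ADP + ppERK	k56		none
R.20	binding	ppMEK + ERK	ppMEK·ERK	a6	d6	none
R.21	binding	ppMEK + pERK	ppMEK·pERK	a6	d6	none
R.22	binding	phosph2 + pERK	phosph2·pERK	a7	d7	none
R.23	catalysis	phosph2·pERK	phosph2 + ERK	k7		none
R.24	binding	phosph2 + ppERK	phosph2·ppERK	a7	d7	none
R.25	catalysis	phosph2·ppERK	phosph2 + pERK	k7		none
R.26	binding	ppMEK + TMT	ppMEK·TMT	a8	d8	tmt
R.27	binding	ppMEK·ATP + TMT	ppMEK·ATP·TMT	a8	d8	tmt
R.28	binding	ppMEK·TMT + ATP	ppMEK·ATP·TMT	a5	d5	tmt
R.29	binding	ppMEK·ERK + TMT	ppMEK·TMT·ERK	a8	d8	tmt
R.30	binding	ppMEK·pERK + TMT	ppMEK·TMT·pERK	a8	d8	tmt
R.31	binding	ppMEK·TMT + ERK	ppMEK·TMT·ERK	a6	d6	tmt
R.32	binding	ppMEK·TMT + pERK	ppMEK·TMT·pERK	a6	d6	tmt
R.33	binding	ppMEK·ATP·ERK + TMT	ppMEK·ATP·TMT·ERK	a8	d8	tmt
R.34	binding	ppMEK·ATP·pERK + TMT	ppMEK·ATP·TMT·pERK	a8	d8	tmt
R.35	binding	ppMEK·ATP·TMT + ERK	ppMEK·ATP·TMT·ERK	a6	d6	tmt
R.36	binding	ppMEK·ATP·TMT + pERK	ppMEK·ATP·TMT·pERK	a6	d6	tmt
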