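# Synthetic consensus-derived motif count matrices.
# Each motif was constructed from its widely cited consensus sequence
# (nuclear-receptor and ER-cofactor motifs: estrogen response element,
# direct repeat 1, forkhead, GATA, AP-1, AP-2 gamma, CTCF core, and the
# AGGTCA nuclear-receptor half-site) by assigning 85 counts to the
# consensus base and 5 to each alternative per position; degenerate 'N'
# positions receive 25 counts per base.  These are stand-ins constructed
# for testing and demonstration, not measured binding data.

>ERE
A:   5   5   5   5  85  25  25  25   5   5  85   5   5
C:   5   5   5  85   5  25  25  25   5   5   5  85  85
G:  85  85   5   5   5  25  25  25   5  85   5   5   5
T:   5   5  85   5   5  25  25  25  85   5   5   5   5

>DR1
A:  85   5   5   5   5  85  25  85   5   5   5   5  85
C:   5   5   5   5  85   5  25   5   5   5   5  85   5
G:   5  85  85   5   5   5  25   5  85  85   5   5   5
T:   5   5   5  85   5   5  25   5   5   5  85   5   5

>FOXA1
A:   5   5   5   5   5  85   5   5   5  85
C:   5   5   5   5   5   5  85   5   5   5
G:   5  85   5   5   5   5   5   5   5   5
T:  85   5  85  85  85   5   5  85  85   5

>GATA3
A:  85   5  85   5  85  85   5  85
C:   5   5   5   5   5   5   5   5
G:   5  85   5   5   5   5  85   5
T:   5   5   5  85   5   5   5   5

>AP-1
A:  85   5   5  85   5   5   5  85   5
C:   5   5   5   5  85   5  85   5   5
G:   5   5  85   5   5   5   5   5   5
T:   5  85   5   5   5  85   5   5  85

>AP2-gamma
A:   5   5   5   5   5  85   5   5   5
C:   5  85  85   5   5   5   5   5  85
G:  85   5   5   5  85   5  85  85   5
T:   5   5   5  85   5   5   5   5   5

>CTCF
A:   5   5  85   5   5  85   5   5   5   5   5   5
C:  85  85   5  85  85   5   5   5   5   5   5  85
G:   5   5   5   5   5   5  85  85   5  85  85   5
T:   5   5   5   5   5   5   5   5  85   5   5   5

>NR-half
A:  85   5   5   5   5  85
C:   5   5   5   5  85   5
G:   5  85  85   5   5   5
T:   5   5   5  85   5   5
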