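#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
S_100                PF01023.24    43 sp|P04271|S100B_HUMAN -             92   1.2e-18   65.1   0.1   1   1   4.1e-22   1.5e-18   64.8   0.1     2    43     5    46     4    46 0.97 S-100/ICaBP type calcium binding domain
EF-hand_1            PF00036.37    29 sp|P04271|S100B_HUMAN -             92   2.3e-08   32.4   0.2   1   1   1.1e-11   2.9e-08   32.1   0.2     1    29    53    81    53    81 0.95 EF hand
#
# Program:         hmmscan
# Synthetic domtblout fixture: hand-written in the HMMER 3.x dialect to carry the
# published S100B domain architecture (S_100 residues 4-46, EF-hand_1 residues 53-81).
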