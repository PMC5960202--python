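#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
f1a_s006             -             80 fam                  -             80   8.8e-59  185.9   2.9   1   1   4.8e-59   9.6e-59  185.8   2.9     1    80     1    80     1    80 0.99 -
f1a_s004             -             81 fam                  -             80   1.2e-58  185.5   4.2   1   1   6.3e-59   1.3e-58  185.4   4.2     1    78     1    78     1    81 0.98 -
f1a_s005             -             80 fam                  -             80   7.9e-58  182.9   5.2   1   1   4.3e-58   8.7e-58  182.7   5.2     1    80     1    80     1    80 0.99 -
f1a_s002             -             80 fam                  -             80   1.1e-57  182.4   2.6   1   1     6e-58   1.2e-57  182.3   2.6     1    79     1    79     1    80 0.99 -
f1a_s007             -             80 fam                  -             80   3.9e-57  180.6   2.0   1   1   2.2e-57   4.3e-57  180.5   2.0     1    80     1    80     1    80 0.99 -
f1a_s001             -             80 fam                  -             80     8e-57  179.6   3.5   1   1   4.4e-57   8.8e-57  179.5   3.5     1    80     1    80     1    80 0.99 -
f1a_s003             -             80 fam                  -             80   2.2e-56  178.2   5.4   1   1   1.2e-56   2.4e-56  178.1   5.4     1    80     1    80     1    80 0.99 -
f1a_s008             -             80 fam                  -             80   1.3e-55  175.7   7.5   1   1   7.4e-56   1.5e-55  175.6   7.5     1    80     1    80     1    80 0.99 -
#
# Program:         hmmsearch
# Version:         3.4 (Aug 2023)
# Pipeline mode:   SEARCH
# Query file:      fam.hmm
# Target file:     db.fasta
# Option settings: hmmsearch --domtblout dom.txt fam.hmm db.fasta 
# Current dir:     /root/pkg/scratch/hmm
# Date:            Sun Sep 20 23:00:11 2026
# [ok]
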