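# CHA node=G0
# foreground: 12 seqs (11.7 weighted)  background: 12 seqs (12.2 weighted)
# pattern columns (1-based): 3,41,62,76
ruler    1         11        21        31        41        51        61        71        81        91        
bars      0801 3   0    2 03     100 00        0 90 0     01 2 31 2 3 9 0 0         7223 0       0212 0 0  20
pattern    *                                     *                    *             *                        
G0_s000  LGMEINRGGGHGGVSDSADQGKQNMVTAYKGTVEQAGSYGGDRICELKPHSIRAMMARNVEATVPHHRDPVNQVIVLAILPSAEDFGGAKVAMEYSFYGQ
G0_s001  GEMGIAAGTGAKGISHSIDIAKIQYENTPFIVLEGSLSGFGMCHPGGFKRKLYLGTVRGLGAATGDHRDGCNVGIVDAMFKGLLDFGVKILLWKHVNDLS
G0_s002  LVLRLAGGAGIGGAVRTLKGDKGTEASYKTQSMENSVVRVGAGALETCRARIGGQTPDILGAQQFLHRDFPNSEVVFPLEDLGVDFGFKSVDGRGHCTDP
fg       2191233!2!12!12221311!31211111212!131131!11112221121423212132!1111!!!22!113822311121!!!2122211211121
bg       0000000!0!00!00000010!00000200010!01100000000000000100000000120000!!!10!001000000000!!!0000000002100
ins      000000000000000000000000000000007000000000000000000000000000000!000000000000000000000000000060000000
del      0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
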