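# Default activation-pathway residue-pair list (38 pairs).
#
# Each line names one pair of generic residue positions whose side-chain
# center distance is a descriptor component; line order defines component
# order.  The pairs connect the conserved class A GPCR activation-pathway
# motifs (CWxP, PIF, sodium pocket, NPxxY, DRY, hydrophobic lock, and the
# G-protein coupling region).  Replace this file to use a different
# descriptor; nothing in the code assumes a particular length.
5x62 6x37
7x45 7x49
3x46 6x37
7x54 8x51
2x50 3x39
2x50 7x49
5x58 6x40
6x40 7x49
5x55 6x41
5x51 6x44
3x43 6x41
3x50 7x53
3x40 6x48
3x40 6x44
5x50 6x44
5x50 6x48
6x48 7x45
3x39 7x45
2x50 7x45
2x50 7x46
3x39 7x49
7x46 7x49
7x49 7x53
7x53 8x50
3x46 7x53
3x46 6x40
3x43 6x44
3x50 6x37
5x58 7x53
3x50 6x30
2x50 3x43
1x50 2x50
1x53 7x53
3x36 6x48
3x36 7x45
5x54 6x40
5x61 6x33
5x65 6x36
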