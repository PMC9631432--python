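# Deposited capsid structures

Place the mmCIF/PDB files of the capsids to analyze here, named by
lower-case PDB id (e.g. `2ms2.cif`).  On a machine with network access:

    tridimer fetch 2MS2 1CWP 1C8N 1AUY

The four ids above are the representative T=3 capsids used by the test
suite: bacteriophage MS2 (Leviviridae), CCMV (Bromoviridae), TNV
(Tombusviridae) and TYMV (Tymoviridae).
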