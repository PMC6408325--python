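# Fetched coordinate files

The deposited-structure regression tests and the `bendkit bend-survey`
examples operate on coordinate files in this directory.  The toolkit never
downloads structures; fetch them yourself, e.g.:

    for id in 6gwc 6gwd 3jak 4hna 4i4t 3ryc 4f6r 4lnu 4drx 4u3j 4ffb 5eyp 5itz 5mio; do
        curl -O https://files.rcsb.org/download/${id}.cif
    done

Name each file by its PDB id (`6gwd.cif`, `3jak.pdb`, ...).  When the
directory contains no structure files, the regression tests skip and the
rest of the suite runs entirely on synthetic fixtures.
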