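# Bundled data

`cosmic_v2_synthetic.tsv` — a **synthetic** stand-in for the COSMIC v2
30-signature reference: 96 trinucleotide-substitution categories x 30
signature profiles (columns sum to 1). Six profiles carry the biologically
motivated peak structure of well-known processes (5-methylcytosine
deamination, APOBEC TCW, tobacco C>A, mismatch-repair deficiency, UV,
APOBEC C>G); the rest are sparse random profiles generated from a fixed seed.
Supply the real COSMIC matrix by path to `mutsig.load_reference_signatures`
/ `cosine_match` for real analyses.
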