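{
  "_comment": [
    "SYNTHETIC reconstruction of the gene 32 mRNA pseudoknot of bacteriophage",
    "T2 (the 2TPK fold): the deposited coordinates are not bundled, so the",
    "28-nt sequence and the two stems were rebuilt from the nucleotide",
    "identities named in published analyses of this pseudoknot (H1 strands",
    "U3..C7 and G16..A20; A8, C19, A20, A22, A24, U25, C26, G27, U28) plus",
    "Watson-Crick complementarity.  Stem pairing registers, not atomic",
    "coordinates; intended for nearest-neighbor stability calculations only."
  ],
  "sequence": "AGUGACCAACGAUGUGGUCAGACAUCGU",
  "numbering_start": 1,
  "helices": {
    "H1": [[3, 20], [4, 19], [5, 18], [6, 17], [7, 16]],
    "H2": [[9, 28], [10, 27], [11, 26], [12, 25], [13, 24], [14, 23], [15, 22]]
  }
}
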