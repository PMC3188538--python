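{
  "version": 1,
  "CAN1_haploid_yeast": {
    "mode": "drake",
    "T": 1773,
    "C": 4.87,
    "C2": 4.53,
    "adjust": 1.0,
    "note": "forward-mutation reporter, haploid S. cerevisiae; constants from the bundled mutator spectrum"
  },
  "URA3_diploid_yeast": {
    "mode": "drake",
    "T": 804,
    "C": 8.18,
    "C2": 6.79,
    "adjust": 1.8,
    "note": "diploid FOA-resistance reporter; external spectrum constants, x1.8 adjusts for lower intrinsic URA3 mutability relative to CAN1"
  },
  "mouse_ouabain": {
    "mode": "target_size",
    "tau": 20,
    "adjust": 1.0,
    "note": "Na,K-ATPase alpha1 ouabain-resistance codons: ~5 bp per allele x 4 alleles in typically tetraploid fibroblasts"
  }
}
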