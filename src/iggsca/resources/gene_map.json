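{
 "n_samples_reference": 231,
 "genes": {
  "SLC6A4": [
   "rs25531"
  ],
  "FKBP5": [
   "rs9296158",
   "rs3800373",
   "rs1360780",
   "rs9470080",
   "rs4713916",
   "rs4713919",
   "rs6902321",
   "rs56311918",
   "rs3798345"
  ],
  "ADCYAP1R1": [
   "rs2267735"
  ],
  "BDNF": [
   "rs6265"
  ],
  "COMT": [
   "rs4680",
   "rs4633"
  ],
  "HTR3A": [
   "rs1062613"
  ],
  "DRD2": [
   "rs2075652"
  ],
  "NR3C1": [
   "rs258747"
  ],
  "OXTR": [
   "rs53576"
  ]
 },
 "snps": {
  "rs25531": {
   "gene": "SLC6A4",
   "wild_genotype": "AA",
   "minor_allele": "G",
   "genotype_counts": [
    174,
    57,
    0
   ],
   "genotype_freqs": [
    0.753247,
    0.246753,
    0.0
   ]
  },
  "rs9296158": {
   "gene": "FKBP5",
   "wild_genotype": "GG",
   "minor_allele": "A",
   "genotype_counts": [
    115,
    98,
    18
   ],
   "genotype_freqs": [
    0.497835,
    0.424242,
    0.077922
   ]
  },
  "rs3800373": {
   "gene": "FKBP5",
   "wild_genotype": "AA",
   "minor_allele": "C",
   "genotype_counts": [
    148,
    71,
    12
   ],
   "genotype_freqs": [
    0.640693,
    0.307359,
    0.051948
   ]
  },
  "rs1360780": {
   "gene": "FKBP5",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    144,
    74,
    13
   ],
   "genotype_freqs": [
    0.623377,
    0.320346,
    0.056277
   ]
  },
  "rs9470080": {
   "gene": "FKBP5",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    111,
    100,
    20
   ],
   "genotype_freqs": [
    0.480519,
    0.4329,
    0.08658
   ]
  },
  "rs4713916": {
   "gene": "FKBP5",
   "wild_genotype": "GG",
   "minor_allele": "A",
   "genotype_counts": [
    146,
    74,
    11
   ],
   "genotype_freqs": [
    0.632035,
    0.320346,
    0.047619
   ],
   "note": "printed hetero and mutant counts were identical and summed past 100%; mutant renormalized to the remainder (231-146-74=11)"
  },
  "rs4713919": {
   "gene": "FKBP5",
   "wild_genotype": "GG",
   "minor_allele": "A",
   "genotype_counts": [
    130,
    82,
    19
   ],
   "genotype_freqs": [
    0.562771,
    0.354978,
    0.082251
   ]
  },
  "rs6902321": {
   "gene": "FKBP5",
   "wild_genotype": "TT",
   "minor_allele": "C",
   "genotype_counts": [
    118,
    97,
    16
   ],
   "genotype_freqs": [
    0.510823,
    0.419913,
    0.069264
   ]
  },
  "rs56311918": {
   "gene": "FKBP5",
   "wild_genotype": "TT",
   "minor_allele": "C",
   "genotype_counts": [
    168,
    59,
    4
   ],
   "genotype_freqs": [
    0.727273,
    0.255411,
    0.017316
   ]
  },
  "rs3798345": {
   "gene": "FKBP5",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    157,
    66,
    8
   ],
   "genotype_freqs": [
    0.679654,
    0.285714,
    0.034632
   ]
  },
  "rs2267735": {
   "gene": "ADCYAP1R1",
   "wild_genotype": "CC",
   "minor_allele": "G",
   "genotype_counts": [
    59,
    119,
    53
   ],
   "genotype_freqs": [
    0.255411,
    0.515152,
    0.229437
   ]
  },
  "rs6265": {
   "gene": "BDNF",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    75,
    108,
    48
   ],
   "genotype_freqs": [
    0.324675,
    0.467532,
    0.207792
   ]
  },
  "rs4680": {
   "gene": "COMT",
   "wild_genotype": "GG",
   "minor_allele": "A",
   "genotype_counts": [
    116,
    102,
    13
   ],
   "genotype_freqs": [
    0.502165,
    0.441558,
    0.056277
   ]
  },
  "rs4633": {
   "gene": "COMT",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    119,
    100,
    12
   ],
   "genotype_freqs": [
    0.515152,
    0.4329,
    0.051948
   ]
  },
  "rs1062613": {
   "gene": "HTR3A",
   "wild_genotype": "CC",
   "minor_allele": "T",
   "genotype_counts": [
    194,
    34,
    3
   ],
   "genotype_freqs": [
    0.839827,
    0.147186,
    0.012987
   ]
  },
  "rs2075652": {
   "gene": "DRD2",
   "wild_genotype": "GG",
   "minor_allele": "A",
   "genotype_counts": [
    86,
    99,
    46
   ],
   "genotype_freqs": [
    0.372294,
    0.428571,
    0.199134
   ]
  },
  "rs258747": {
   "gene": "NR3C1",
   "wild_genotype": "AA",
   "minor_allele": "G",
   "genotype_counts": [
    125,
    89,
    17
   ],
   "genotype_freqs": [
    0.541126,
    0.385281,
    0.073593
   ]
  },
  "rs53576": {
   "gene": "OXTR",
   "wild_genotype": "AA",
   "minor_allele": "G",
   "genotype_counts": [
    92,
    99,
    40
   ],
   "genotype_freqs": [
    0.398268,
    0.428571,
    0.17316
   ]
  }
 }
}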