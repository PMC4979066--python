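{
  "expected_ou_scan.tsv": "764f39de3aae48d21971321231caf1efdc84c2ef45ffef6636a8033fc9ea0222",
  "expected_rrbl.tsv": "00017595ded44dfc96b9825288197cf28543a913cd9cbefb79cccf096a1e0d1e",
  "expression.tsv": "2f77b40b2949fb7815075562ee33c6412a400efe44a406fc6402a397117f9e81",
  "sample_map.tsv": "87c0aa82503f99de4ecd5259f534f2c7b9bc0f4164720138286e93d780e6adeb",
  "seq_tree.nwk": "23a59331117c3f60c3fd1cd47528b420cddbde5080763b3fd12972c4f93e3aff",
  "tree.nwk": "ca5e7ae6382d41152152999ca4d258ab8009de28d2ca7cdcfd87d2eaced62bcd"
}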