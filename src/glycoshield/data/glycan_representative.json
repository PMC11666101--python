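{
  "name": "core-fucosylated biantennary, one terminal Neu5Ac",
  "n_linked": true,
  "root": "GlcNAc-1",
  "nodes": [
    {"id": "GlcNAc-1", "monosaccharide": "GlcNAc"},
    {"id": "Fuc-core", "monosaccharide": "Fuc"},
    {"id": "GlcNAc-2", "monosaccharide": "GlcNAc"},
    {"id": "Man-3", "monosaccharide": "Man"},
    {"id": "Man-A", "monosaccharide": "Man"},
    {"id": "Man-B", "monosaccharide": "Man"},
    {"id": "GlcNAc-A", "monosaccharide": "GlcNAc"},
    {"id": "GlcNAc-B", "monosaccharide": "GlcNAc"},
    {"id": "Gal-A", "monosaccharide": "Gal"},
    {"id": "Gal-B", "monosaccharide": "Gal"},
    {"id": "Neu5Ac-A", "monosaccharide": "Neu5Ac"}
  ],
  "linkages": [
    {"parent": "GlcNAc-1", "child": "Fuc-core", "anomeric": "alpha", "donor": 1, "acceptor": 6},
    {"parent": "GlcNAc-1", "child": "GlcNAc-2", "anomeric": "beta", "donor": 1, "acceptor": 4},
    {"parent": "GlcNAc-2", "child": "Man-3", "anomeric": "beta", "donor": 1, "acceptor": 4},
    {"parent": "Man-3", "child": "Man-A", "anomeric": "alpha", "donor": 1, "acceptor": 3},
    {"parent": "Man-3", "child": "Man-B", "anomeric": "alpha", "donor": 1, "acceptor": 6},
    {"parent": "Man-A", "child": "GlcNAc-A", "anomeric": "beta", "donor": 1, "acceptor": 2},
    {"parent": "Man-B", "child": "GlcNAc-B", "anomeric": "beta", "donor": 1, "acceptor": 2},
    {"parent": "GlcNAc-A", "child": "Gal-A", "anomeric": "beta", "donor": 1, "acceptor": 4},
    {"parent": "GlcNAc-B", "child": "Gal-B", "anomeric": "beta", "donor": 1, "acceptor": 4},
    {"parent": "Gal-A", "child": "Neu5Ac-A", "anomeric": "alpha", "donor": 2, "acceptor": 6}
  ]
}
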