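{
  "description": "Packaged default 16-seed Voronoi tessellation of the virtual C-alpha dihedral pair space (gamma_{i-1}, gamma_i), radians; the information-optimal seeds derived from a large non-redundant X-ray structure set.",
  "metric": "euclidean",
  "seeds": [
    [0.0, 2.4],
    [0.3, 2.8],
    [0.6, 5.9],
    [1.8, 3.8],
    [1.9, 2.2],
    [2.1, 1.5],
    [2.2, 5.7],
    [2.5, 2.1],
    [2.6, 2.1],
    [3.0, 1.3],
    [4.6, 4.0],
    [4.6, 0.9],
    [4.7, 6.0],
    [4.8, 5.0],
    [4.9, 2.5],
    [6.1, 6.0]
  ]
}
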