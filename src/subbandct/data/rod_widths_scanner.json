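{
  "description": "Scanner-derived Gaussian PSF widths measured with 1 mm aluminium rods on a clinical fan-beam CT system (120 kV, 100 mAs, 1440 views, 912 cells of 1.09 mm). These values were NOT produced by this package's simulator; they ship only as a realistic fixture for the rational kernel-width model fit.",
  "offsets_cm": [0, 7, 14, -7, -14],
  "sigma": [0.1, 0.4, 0.95, 1.0, 1.1],
  "width_unit": "pixel",
  "note": "Widths are paired with offsets in the order printed by the source measurement. Under the convention that positive offsets lie toward the detector (source distance D + offset), this pairing is non-monotonic in source distance; see docs/methods.md for the two possible pairings."
}
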