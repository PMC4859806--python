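{
  "description": "Synthetic stand-in for the fixed, zero-parameter non-monotonic short-range quenching curve (scheme Q1). The published curve from the cited prior work is not reproduced here; this lookup is a documented placeholder with the qualitative shape described in the literature: moderate quenching at very short range, a peak near 50 bp, and decay to zero beyond ~100 bp. Users can supply their own table via configuration.",
  "synthetic": true,
  "bin_width": 10,
  "values": [0.35, 0.45, 0.55, 0.7, 0.85, 0.95, 0.8, 0.6, 0.4, 0.2],
  "beyond": 0.0
}
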