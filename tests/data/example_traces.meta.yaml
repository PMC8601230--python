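eggs:
  NC_000:
    group: NC
    replicate: r1
    stimulus_time_s: 60.0
  NC_001:
    group: NC
    replicate: r2
    stimulus_time_s: 60.0
  SOV_000:
    group: SOV
    replicate: r1
    stimulus_time_s: 60.0
  SOV_001:
    group: SOV
    replicate: r2
    stimulus_time_s: 60.0
mode: strontium
provenance: simulated
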