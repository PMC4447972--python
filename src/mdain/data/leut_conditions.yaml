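# Inventory of the LeuT MD conditions analysed by this package's reference
# study design: condition name encodes construct (WT / mutant), bound cation
# (Na or Li) and substrate state (Leu / Ala / ns = no substrate).
# lengths_ns lists the declared duration of each replica; only the per-condition
# totals are fixed by the study design, so single-replica conditions carry the
# total and multi-replica conditions split it evenly for bookkeeping purposes.
conditions:
  - {name: WT.Na.Leu,    n_replicas: 2, total_ns: 590}
  - {name: WT.Na.Ala,    n_replicas: 1, total_ns: 360}
  - {name: WT.Na.ns,     n_replicas: 3, total_ns: 3600}
  - {name: WT.Li.Leu,    n_replicas: 1, total_ns: 480}
  - {name: WT.Li.Ala,    n_replicas: 1, total_ns: 480}
  - {name: WT.Li.ns,     n_replicas: 2, total_ns: 2400}
  - {name: Y268A.Na.Leu, n_replicas: 1, total_ns: 600}
  - {name: Y268A.Na.ns,  n_replicas: 3, total_ns: 4320}
  - {name: R5A.Na.ns,    n_replicas: 2, total_ns: 2640}
  - {name: D369A.Na.ns,  n_replicas: 3, total_ns: 2480}
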