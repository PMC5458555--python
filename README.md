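# mxfret

Analysis of two-colour single-molecule FRET (smFRET) time traces, built
around the workflow used to study the conformational dynamics of
dynamin-family GTPases such as the antiviral protein MxA: a surface-tethered
molecule carries a donor/acceptor dye pair across a domain interface, and
the per-frame FRET efficiency

    E = I_A / (I_D + I_A)

reports the inter-dye distance in real time.  The GTPase-domain/BSE
interface of MxA ("AS" labelling construct) exchanges between an open
(E ≈ 0.35) and a closed (E ≈ 0.72) conformation; the BSE/stalk interface
("RR" construct) visits three states (E ≈ 0.35 / 0.55 / 0.85) with direct
low↔high exchange essentially absent; a hinge-bracket point mutant (R640A)
collapses either construct onto a single high-FRET state.

The package covers the whole pipeline, every stage testable by parameter
recovery on simulated data:

* **`mxfret.simulate` / `mxfret.presets`** — ground-truthed trace generator:
  K-state Markov dynamics, Gaussian FRET emission converted to
  anti-correlated channel intensities, 7.5% donor→acceptor bleed-through,
  additive channel noise, exponential single-step photobleaching of each
  dye, optional aggregates and donor-only molecules.  Named presets encode
  construct × nucleotide conditions (`AS_apo`, `AS_GMPPCP`, `RR_apo`,
  `RR_R640A`, …).
* **`mxfret.qc`** — automatic single-molecule selection: exactly one
  catastrophic photobleach in the median-filtered (9-frame) total intensity
  (a drop ≥ 3 background s.d. that never recovers), signal-to-background
  ≥ 8:1, donor–acceptor Pearson correlation < 0; bleed-through correction
  and per-frame FRET over the pre-bleach window.
* **`mxfret.hmm`** — one global K-state Gaussian-emission hidden Markov
  model per condition, fitted by Baum–Welch over all selected traces
  jointly, with multi-restart EM and Viterbi idealization.
* **`mxfret.stats`** — FRET histogram with Gaussian decomposition and
  trace-bootstrap error bars, state occupancies, censored dwell-time
  summaries, transition density plots, donor–acceptor cross-correlation.
* **`mxfret.registration`** — affine donor→acceptor channel mapping from
  matched fiducial beads.
* **`mxfret.pipeline` / `mxfret` CLI** — end-to-end per-condition runs with
  delimited-text artifacts and a JSON summary.

## Worked example

`examples/condition_report.py` simulates 100 traces each for a quiescent
condition (`AS_apo`, rare transitions, high-FRET state preferred) and a
dynamic one (`AS_GMPPCP`, second-scale exchange), runs the full pipeline on
both and compares them.  Output:

```
=== AS_apo ===
traces passing QC: 85/100
mixture means: [0.349 0.72 ] (weights [0.27 0.73])
high-state occupancy: 72.5% of frames
cross-correlation amplitude: 0.207

=== AS_GMPPCP ===
traces passing QC: 87/100
mixture means: [0.338 0.722] (weights [0.58 0.42])
high-state occupancy: 42.3% of frames
mean dwells: [1.   0.75] s +- [0.034 0.022] (bootstrap)
cross-correlation amplitude: 0.760
```

Reading the numbers: both conditions resolve the same two conformations
(mixture means ≈ 0.35 / 0.72); the nucleotide-free molecule spends ~70% of
its time closed (high FRET) and shows a small donor–acceptor
anti-correlation amplitude because transitions are rare, whereas the
GTP-analogue condition actively switches (mean dwells ≈ 1.0 s / 0.8 s) and
its anti-correlation amplitude is several-fold larger — the signature of
nucleotide-activated domain motion.  Traces failing selection are mostly
molecules that outlived the recording without a photobleach step.

The other examples (`simulate_and_screen.py`, `idealize_traces.py`,
`register_channels.py`) each demonstrate one stage in isolation.

A thin CLI wraps the same calls:

```sh
mxfret simulate --preset AS_GMPPCP --n 200 --seed 7 --out traces.tsv
mxfret qc --in traces.tsv --out qc.tsv --fret fret.tsv
mxfret fit --fret fret.tsv --k 2 --seed 7 --model-out model.json
mxfret run --traces traces.tsv --out report/ --condition AS_GMPPCP --k 2 --seed 7
```

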