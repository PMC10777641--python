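# ecaploop

Evoked compound action potential (ECAP) analysis and closed-loop spinal cord
stimulation (SCS) dosing, with a fully synthetic plant so every stage runs
without any external data.

The package simulates multi-contact epidural recordings of triphasic ECAPs
(P1/N1/P2) in freely behaving animals — linear fiber recruitment above a
current threshold, exponential amplitude fall-off with distance, finite
conduction velocity, slow posture-like gain disturbances — and implements
the analysis chain used on such recordings:

| module | what it does |
| --- | --- |
| `ecaploop.synth` | ground-truth-parameterized recordings, gain traces, behavior tables |
| `ecaploop.features` | P1/N1/P2 latency + N1–P2 amplitude extraction, detectability |
| `ecaploop.iofit` | recruitment (input–output) curve fit: smoothing spline → linear regression → extrapolated ECAP threshold, slope, R², 0–1 current normalization, MT:ECAPT ratio |
| `ecaploop.cv` | conduction velocity from N1 latency vs contact distance (onset-delay invariant) |
| `ecaploop.cloop` | open- vs closed-loop session simulation (one integral controller update per pulse), 3-SD outlier exclusion, dosing summaries |
| `ecaploop.behavior` | von Frey / acetone endpoints, two-way ANOVA with Welch + Bonferroni post-hocs, windowed AUC |
| `ecaploop.io`, `ecaploop.cli`, `ecaploop.config` | HDF5/CSV/YAML round-trips, CLI entry points, serializable run config |

Units throughout: currents mA, voltages mV, in-sweep time ms, distances mm,
conduction velocity m/s.

## CLI

The console script `ecaploop` exposes the pipeline:

```sh
ecaploop simulate   --seed 1 --out run/            # synthetic IO sweep + behavior table
ecaploop features   --recording run/recording.h5 --out run/
ecaploop iofit      --features run/features.csv --mt 0.082 --out run/
ecaploop cv         --recording run/recording.h5 --out run/
ecaploop closedloop --seed 1 --mode both --duration-min 30 --out run/
ecaploop behavior   --table run/behavior.csv --out run/
ecaploop replicate  --seed 1 --out run/            # built-in fixture checks, exit 0 on pass
```

Every subcommand echoes its effective configuration to
`<out>/config_used.yaml`; identical config + seed reproduces identical
artifacts bit for bit.

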