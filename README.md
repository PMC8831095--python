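# nodeloc — RSS-based trilateration for radio-telemetry node networks

`nodeloc` turns the raw detection logs of an automated radio tracking system
(ARTS) — a network of fixed, omnidirectional radio receivers ("nodes") that
log tag id, received signal strength (RSS, dB) and a timestamp for every
pulse of an animal-borne VHF transmitter — into location estimates, and
quantifies how accurate those estimates are for alternative network designs.
It is written for movement ecologists running node networks to track
fine-scale animal movement at landscape scale, where vegetation and
structures make radio propagation noisy.

## The method

**Signal-to-distance model.** RSS decays with distance following a negative
exponential with a noise-floor asymptote,

    RSS(d) = a · exp(−S·d) + K,

where `a` is the intercept (dB above the floor at zero distance), `S` the
decay rate (per metre) and `K` the horizontal asymptote (dB).  The curve is
fitted to calibration data — window-averaged RSS at known node-transmitter
distances — by nonlinear least squares, and inverted in closed form,
`d = −ln((RSS − K)/a)/S`, to convert each node's mean RSS into an estimated
range.

**Filtered trilateration.**  Each detecting node constrains the transmitter
to a circle of radius equal to its estimated range.  The location estimate
minimizes the range-residual objective

    f(x, y) = Σᵢ ( ‖(x, y) − nodeᵢ‖ − dᵢ )²

by a Gauss–Newton iteration seeded at the node with the strongest signal
(at least 3 non-coincident nodes required).  Because far nodes report RSS
near the asymptote — where RSS carries almost no distance information —
using *all* nodes drags estimates toward the network centroid.  Two node
exclusion filters counter this:

- **RSS filter** — keep nodes whose mean RSS exceeds a dB cutoff
  (e.g. −80 … −95 dB);
- **distance filter** — keep nodes within a radius (a multiple of the
  average network spacing, e.g. 1.25× … 4×) of the strongest-signal node.

**Simulation framework.**  To choose a network design and filter before
deploying hardware, the package simulates node grids (uniform 100/175/250 m
spacing, or one node randomized per grid cell) over a 1250 m study square,
scatters random test locations, draws per-node RSS from the decay curve plus
Gaussian noise (σ = 6 dB) and distance-dependent logistic detection dropout
(or by resampling a field calibration table), and localizes every draw under
every filter — a paired design, 100 locations × 1000 replicates per
configuration.  Summaries report location loss (realizations with < 3
retained nodes), mean retained-node counts, and localization error
(true-to-estimate distance) with cluster-bootstrap confidence intervals, plus
error profiles against distance-to-network-edge to quantify edge effects.

## Worked example

Generate synthetic fixtures (a calibration campaign, a 25-node 100 m grid
and a detection log for one tag at three stationary spots), then run the
pipeline:

```sh
nodeloc make-fixtures --out-dir fixtures --seed 0
nodeloc fit --calibration fixtures/calibration.csv --out model.json
```

    fitted decay model: a=47.6290 S=0.005141 K=-105.0057 (residual sd 3.05 dB, n=1360)

The fitted parameters recover the curve that generated the fixtures
(a = 47.23, S = 0.005, K = −105.16) to within the noise.  Localize the tag
with a 1.25× distance filter, averaging RSS over 5-minute windows:

```sh
nodeloc localize --nodes fixtures/nodes.csv --detections fixtures/detections.csv \
    --model model.json --filter dist:1.25 --window 300 --stride 300 --out estimates.csv
```

    3 windows, 25 nodes, filter=dist_1.25x, 0 without an estimate -> estimates.csv

The three window estimates, (121.6, 136.9), (220.9, 260.0) and
(329.2, 178.1), land within ~10 m of the true transmitter spots (120, 140),
(210, 260) and (330, 180).  Finally, simulate a small experiment on a 250 m
grid and summarize:

```sh
nodeloc simulate --config fixtures/sim.yaml --out results.csv --summary summary.csv
```

        filter  pct_location_loss  mean_n_nodes  mean_error_m  median_error_m
    dist_1.25x                0.0          4.24        108.42           86.38
          none                0.0         15.70        145.42          137.59
     rss_-90dB               17.5          3.72         92.48           73.60

Reading the table: the unfiltered estimate uses ~16 nodes and has a median
error of ~138 m; the 1.25× distance filter cuts that to ~86 m using ~4
nodes and loses no locations, while the −90 dB RSS filter is similarly
accurate but fails to produce an estimate for 17.5% of realizations (fewer
than 3 nodes above the cutoff).  At the full simulation scale the contrasts
sharpen considerably; this demonstration config uses 10 locations × 20
replicates so it runs in seconds.

## Layout

| module | contents |
|---|---|
| `nodeloc.propagation` | decay model, NLS fit, closed-form inversion |
| `nodeloc.detections` | detection-log windowing, trimming, per-node averaging |
| `nodeloc.localization` | node networks, RSS/distance filters, Gauss–Newton trilateration |
| `nodeloc.simulation` | network layouts, noise/dropout models, paired experiments |
| `nodeloc.evaluation` | error summaries, bootstrap CIs, edge-effect profiles |
| `nodeloc.io` / `nodeloc.cli` | CSV/JSON/YAML interfaces and the `nodeloc` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
their calibration, and known limitations.
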