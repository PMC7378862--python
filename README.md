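# qwa — quantitative wood anatomy of defoliator-outbreak impacts

`qwa` is a Python library for dendroanatomists and forest ecologists who
want to quantify how insect defoliation reshapes conifer tree rings — not
just how much narrower the rings get, but what happens to the cells
inside them. It takes tracheid-level measurements (the kind exported by
image-analysis tools such as ROXAS), derives cell and ring functional
traits, builds detrended chronologies, detects outbreak years against a
non-host climate control, and quantifies immediate and multi-year legacy
effects with superposed-epoch statistics and intra-ring profiles. A
synthetic tracheidogram generator with full ground truth supports every
calibration and recovery analysis.

## The science in brief

Per tracheid, from the radial lumen diameter (CLD), lumen area (CLA),
wall thicknesses and wall area (CWA):

- mean wall thickness **CWT** = (radial + tangential)/2,
- total cell area **CTA** = CLA + CWA,
- relative anatomical density **CWD** = CWA/(CLA + CWA),
- theoretical hydraulic conductivity of the cell, treating the lumen as
  an elliptical tube under Hagen–Poiseuille flow:

  **Kh_c = π a³ b³ / (4 η (a² + b²))**,

  with radial semi-axis a = CLD/2, tangential semi-axis b from the
  ellipse-area relation CLA = π a b, and η the viscosity of water
  (1.002 × 10⁻⁹ MPa s at 20 °C). With a = b = r this is the classical
  π r⁴ / (8 η).

Per ring, the *average radial file* (per-rank means across radial files
on a common [0, 1] rank scale) gives the mean cells per file **CN** and:

- **RWA** (ring wall area) = CN × mean CWA of the average file — the
  ring's woody biomass proxy (and, at 50.8 % wall carbon, its structural
  carbon proxy),
- **Kh_r** = CN × mean Kh_c — the ring's theoretical hydraulic
  conductivity,
- **HCUE** = Kh_r / RWA — hydraulic conductivity bought per unit of
  carbon invested in walls.

Chronologies are ratio indices against a cubic smoothing spline with a
50 % frequency cutoff at 100 years, combined across trees by Tukey's
biweight robust mean. Outbreak start years are wall-thickness declines
> 10 % below the previous five-year mean in the host that are *not*
mirrored by the non-host (which shares the climate but not the
defoliator). Epoch analysis expresses each parameter in relative years
1…8 after each event as a deviation ratio against the fixed five-year
pre-event reference, tested with Welch's t; intra-ring loess profiles
(with standard-error envelopes) localize the damage within the ring.

## Worked example

```python
import qwa

host, nonhost, climate, _ = qwa.simulate_pair(seed=7)   # shared climate
host_cwt = qwa.detrend_and_build(host, "mean_CWT", site_id="S19")
nonhost_cwt = qwa.detrend_and_build(nonhost, "mean_CWT")
events = qwa.classify_severity(
    qwa.detect_outbreaks(host_cwt.index, nonhost_cwt.index, site_id="S19")
)
print(qwa.events_to_frame(events))
```

```
  site_id  start_year severity  first_year_cwt_ratio
0     S19        1908     high              0.726114
1     S19        1915      low              0.862480
2     S19        1935      low              0.881312
3     S19        1945     high              0.711523
4     S19        1954      low              0.852811
5     S19        1963     high              0.723349
6     S19        1972     high              0.752723
7     S19        1981      low              0.852869
```

All eight injected outbreaks are recovered; the first-year CWT ratio is
the relative wall-thickness decline (0.73 = a 27 % drop), and the
strongest half are labelled high severity. Continuing with the epoch
analysis on the same simulation (`examples/04_epoch_analysis.py`) gives
year-1 deviations of about −53 % for cell number, −25 % for wall
thickness and −2 % for lumen diameter, a −59 % drop in ring hydraulic
conductivity, a −65 % drop in ring wall area (biomass), and a ring-width
based loss estimate about 8.5 percentage points milder than the
anatomy-based one — cell division suffers most, cell enlargement least,
and ring width alone understates the biomass loss.

The `examples/` directory holds one short script per capability
(traits, simulation, detection, epoch analysis, intra-ring profiles,
climate correlations); each prints the numbers it computes and a line on
what they mean. A thin CLI mirrors the stages:
`qwa simulate|traits|chronology|detect|epoch|climate|report`.

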