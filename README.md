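# noisepop

Population health impacts of aircraft noise exposure, end to end: from 1-Hz
sound-level time series and gridded noise-exposure surfaces to the number of
people at risk of annoyance, sleep disturbance, hearing impairment and delays
in childhood learning.

The package is aimed at acousticians, exposure scientists and community
groups assessing aviation noise — particularly the intense, intermittent
regimes around military airfields — who need a transparent, reproducible
alternative to black-box assessment chains.

## What it computes

**Acoustic metrics** (`noisepop.metrics`). From A-weighted 1-s equivalent
levels L<sub>Aeq,1s</sub>: the day-night average level
L<sub>dn</sub> (24-h energy average with a +10 dB penalty on 22:00–07:00),
L<sub>den</sub> (additionally +5 dB on 19:00–22:00), the nighttime average
L<sub>night</sub>, L<sub>eqH</sub> over arbitrary intervals, hourly
L<sub>eq</sub>, the residual-sound estimator L<sub>95</sub> (level exceeded
95 % of the time, nearest-rank rule), the monthly energy average
L<sub>dnmr</sub> for special-use airspace, and OSHA/NIOSH occupational noise
doses with a 24-h reference duration. All decibel arithmetic is carried out
in the energy domain, 10^(L/10), in double precision.

**Event detection** (`noisepop.events`). Overflights are detected from the
10-s moving energy average of the 1-s series against an adaptive threshold
max(L95 of the surrounding hour + 15 dB, 50 dB); an event ends after 5 s
below threshold, detections are discarded unless the raw maximum clears the
residual level by 15 dB, and multi-peak detections are subdivided at the
minimum between prominent peaks. Per-event metrics: sound exposure level
L<sub>E</sub> (SEL), L<sub>max</sub>, optional L<sub>Fmax</sub> and
L<sub>Cpeak</sub>, and onset rate in dB/s.

**Exposure-response curves** (`noisepop.curves`). A validated YAML registry
of seven published curves: percent highly annoyed versus L<sub>dn</sub>
(FICON, ISO 1996-1, WHO 2018, FAA NES, Yokoshima military-aircraft
synthesis) and percent highly sleep disturbed versus L<sub>night</sub>
(WHO 2018, Smith update). Levels above a curve's domain are capped at the
domain-top response; levels below contribute zero. The WHO learning-delay
rule for schools (1 month of reading delay at 55 dB, 1–2 further months per
5 dB) and the threshold set (45 dB L<sub>dn</sub> adverse effects, 40 dB
L<sub>night</sub> sleep, 70 dBA L<sub>eq24</sub> hearing, 65 dB
L<sub>dn</sub> land-use incompatibility, 55 dB L<sub>dn</sub> schools) live
here too.

**Dasymetric population mapping** (`noisepop.population`). Census-block
populations are distributed over the 30-m cells of developed,
non-transportation land cover inside each block (equal split, cell-centre
assignment, uniform fallback for blocks without impervious cover), conserving
population mass exactly. Noise-contour polygons are rasterized to the same
grid and intersected with the population to give exposure histograms and
per-region threshold summaries; overlapping tribal regions are reported
independently of their host counties.

**Impact pipeline** (`noisepop.pipeline`). Per-cell outcome accounting
(response percent × cell population, summed per region), school-point
impacts, hearing-risk counts, and an operations-scaling sweep in which
scaling all flight operations by a factor k shifts every surface by
10·log₁₀(k) dB — the exact consequence of multiplying event counts under
energy-additive metrics.

**Synthetic study worlds** (`noisepop.synth`). Seeded generators for every
input: jittered ambient plus fast-onset/slow-decay overflight events with
exact ground truth, a 70/20/10 day/evening/night operations schedule,
point-source noise surfaces with geometric spreading and absorption, Voronoi
census blocks with urban/rural impervious contrast, regions and schools.

## Worked example

```python
from noisepop import load_curve_registry
from noisepop.synth import gen_world, LC_DEVELOPED, LC_TRANSPORT
from noisepop.population import impervious_mask, distribute_population
from noisepop import pipeline as pl

world = gen_world(seed=42)                      # 200x200 cells, 30 m, 2 airfields
mask = impervious_mask(world.census.landcover, {LC_DEVELOPED}, {LC_TRANSPORT})
pop = distribute_population(world.census.blocks, mask, world.spec)

exposed = pl.exposed_population(pop, world.surfaces["Ldn"], 45.0,
                                world.census.regions)
for o in exposed:
    print(f"{o.region_id}: exposed {o.persons:.0f} ({o.percent_of_region:.1f}%)")

who = next(c for c in load_curve_registry() if c.name == "WHO")
ha = pl.estimate_outcome(pop, world.surfaces["Ldn"], who, world.census.regions)
print("WHO highly annoyed:", round({o.region_id: o.persons for o in ha}["Total"]))
```

prints

```
West County: exposed 19011 (96.1%)
East County: exposed 28072 (92.9%)
Tribal Area: exposed 1361 (100.0%)
Total: exposed 47083 (94.2%)
WHO highly annoyed: 13397
```

i.e. of the 50,000 synthetic residents, 47,083 live on cells at or above the
45 dB L<sub>dn</sub> adverse-effect threshold, and weighting each cell's
population by the WHO annoyance curve at its exposure level predicts 13,397
people highly annoyed. The overlapping tribal region is reported on its own
row; the total is computed over the whole raster.

A command-line interface mirrors the library
(`noisepop synth|metrics|detect|population|impacts|scenario|run`), driven by
a YAML config for end-to-end runs; all outputs are plain text (CSV, GeoJSON,
ASCII grids) and byte-reproducible from config + seed.

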