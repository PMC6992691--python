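"""Assess one species end to end on the bundled demo fixture world.

Builds the offline fixture world (name backbone, checklist ranges,
occurrence service, stylised region tiles) in a temporary directory and
runs the full single-species workflow for Aloe zebrina: name match →
native range → occurrence fetch → native filter → range statistics →
Least Concern gauges.
"""

import tempfile

from lcscreen import LCThresholds, gen_fixture_suite, load_fixture_backends, run_single

with tempfile.TemporaryDirectory() as d:
    gen_fixture_suite(d, seed=0)
    backends = load_fixture_backends(d)
    result = run_single("Aloe zebrina", backends, thresholds=LCThresholds())

taxon = result.taxon
m, g = taxon.metrics, taxon.gauge
print(f"best match : {taxon.match.canonical_name} {taxon.match.authorship} "
      f"({taxon.match.family}, confidence {taxon.match.confidence:.0f})")
print(f"native range: {sorted(taxon.native_range.native_codes)}")
print(f"filtered out: {taxon.occurrences.removed_count} non-native/duplicate points")
print(f"EOO         : {m.eoo_km2:,.0f} km^2   (threshold 30,000; pass={g.eoo_pass})")
print(f"AOO         : {m.aoo_km2:,.0f} km^2   (threshold 3,000; pass={g.aoo_pass})")
print(f"records     : {m.record_count}        (threshold 75; pass={g.records_pass})")
print(f"regions     : {m.tdwg_count}          (threshold 5; pass={g.tdwg_pass})")
print(f"likely Least Concern: {g.least_concern}")
# EOO is the convex-hull area of the native-filtered points; AOO counts
# occupied 10 km grid cells x 100 km^2. The species passes all four gauges,
# so it is flagged as a likely Least Concern candidate for human review.
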