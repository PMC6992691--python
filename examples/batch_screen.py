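"""Batch-screen a name list and export the assessment bundle.

The batch workflow pre-screens names against the checklist (synonyms and
unknown names are excluded with an explanation), assesses the accepted
species, and documents every species that passed the Least Concern
screen as a SIS Connect-style multi-CSV bundle plus a point file.
"""

import tempfile
from pathlib import Path

from lcscreen import (
    build_bundle,
    gen_fixture_suite,
    load_fixture_backends,
    results_to_frame,
    run_batch,
    validate_bundle,
    write_bundle,
)
from lcscreen.taxa import TaxonQuery, load_batch_names

with tempfile.TemporaryDirectory() as d:
    paths = gen_fixture_suite(d, seed=0)
    backends = load_fixture_backends(d)
    queries = load_batch_names(paths["names"])
    result = run_batch(queries, backends)

    print("screen report:",
          f"{len(result.report.accepted)} accepted,",
          f"{len(result.report.excluded_synonyms)} synonyms excluded,",
          f"{len(result.report.unmatched)} unmatched")
    print(results_to_frame(result.rows).to_string(index=False))

    bundle = build_bundle(result.lc_taxa)
    print("bundle violations:", validate_bundle(bundle))
    out = write_bundle(bundle, Path(d) / "bundle")
    print("tables written:", sorted(p.name for p in out.csv_paths.values()))
# Each results row carries the four range statistics and the LC verdict;
# synonyms and unmatched names keep a warning instead of metrics. Only
# species with least_concern=True enter the assessment bundle.
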