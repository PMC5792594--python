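"""Simulate a 13-species study with planted gene families.

Builds the default design (5 ingroup + 8 outgroup species on a guide
tree), plants one shared family (4 subfamilies) and one clade-specific
family (2 subfamilies, ingroup only) plus 40 decoy proteins, and writes
the bundle to plain-text fixture files.
"""

import tempfile
from pathlib import Path

from clademiner.simulate import simulate_bundle, write_fixture

bundle = simulate_bundle(seed=1)

n_planted = len(bundle.truth.domain_bearing())
n_total = len(bundle.truth.genes)
print(f"species: {len(bundle.proteomes)}")
print(f"genes: {n_total} total, {n_planted} planted family members, "
      f"{n_total - n_planted} decoys")
print(f"subfamilies planted: {len(bundle.truth.subfamily_specific)} "
      f"({sum(bundle.truth.subfamily_specific.values())} clade-specific)")
print(f"pathway genes (planted highly expressed): {bundle.truth.pathway_genes}")
print(f"expression table: {bundle.expression.values.shape[0]} genes x "
      f"{bundle.expression.values.shape[1]} samples (5 wild + 6 cultivated)")

outdir = Path(tempfile.mkdtemp()) / "fixture"
files = write_fixture(bundle, outdir)
print(f"wrote {len(files)} fixture files under {outdir}")
# The truth table records every planted label, so downstream stages can be
# scored for sensitivity/specificity against a known answer.
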