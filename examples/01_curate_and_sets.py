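"""Curate a compound table and assemble the gut compound sets.

Generates a small synthetic library, writes it as a CSV in the reader
schema, then runs the curation chain: read + normalize structures,
deduplicate across sources, assign compartment sets (Gut / GutSerum /
Serum / DrugBank), reassign fatty-lipid GutSerum records to Gut, split
Gut into FL / noFL, and attach the Traverser/Lingerer permanence labels.
"""

import tempfile
from pathlib import Path

from gutperm import assemble, deduplicate_across_sets, read_compound_table
from gutperm.synthetic import BenchmarkSpec, generate_benchmark, write_benchmark

out = Path(tempfile.mkdtemp())
spec = BenchmarkSpec(n_fl=60, n_nofl=40, n_traverser=50, seed=1)
records, truth = generate_benchmark(spec)
write_benchmark(records, truth, out, spec)

records = read_compound_table(out / "compounds.csv", "hmdb_gut")
records = deduplicate_across_sets(records)
records, report = assemble(records)

print(f"curated records: {len(records)}")
print(f"set sizes:       {report.sizes}")
print(f"moved FL GutSerum -> Gut: {report.moved_fl}")

# The Lingerer count is |Gut-FL| + |Gut-noFL|: molecules that stay in the
# gut lumen; Traversers (DrugBank + GutSerum) cross the gut wall.
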