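"""Generate a planted bifurcating-lineage dataset, write it as a 10x-style
fixture, and run cell quality control.

The simulator plants six mesenchymal populations (EMP -> LMP -> LCP forking
to OB -> Ocy and AD) with negative-binomial UMI counts, cycling progenitors,
and mitochondrial genes. QC removes cells with > 6000 or < 200 detected
genes or > 5% mitochondrial UMIs.
"""

from pathlib import Path

import mesentrace as mt

params = mt.SimParams(n_cells_per_population=200, n_genes=800, seed=1)
counts, truth = mt.simulate_dataset(params)
out = Path("scratch/example_fixture")
paths = mt.write_fixture(counts, truth, out)
print(f"fixture written to {out}: {sorted(p.name for p in out.iterdir())}")

reread = mt.read_10x_mtx(out)
filtered, qc = mt.qc.qc_filter(reread)
n_fail = int((~qc.pass_mask).sum())
print(f"cells: {reread.n_cells} simulated, {filtered.n_cells} pass QC, {n_fail} removed")
print(qc.table[~qc.table["pass_flag"]].head().to_string(index=False))
print(
    "# Removed cells violate one of the three rules above; median pct_mito of "
    f"passing cells is {qc.table.loc[qc.table['pass_flag'], 'pct_mito'].median():.2f}%."
)
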