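"""Reticulation morphometrics: cell areas and transverse costa counts.

Generates one reticulate (pattern C) and one dense (pattern A) synthetic
elytron, measures the enclosed cell areas from the cell-bottom masks and
counts transverse costae along a longitudinal transect.  Reticulate
elytra have a few large cells; dense elytra many small ones — the
structural basis of the reticulate warning signal.
"""

from elytra import boxplot_stats, count_transverse, measure_cells
from elytra.simulate import ElytronSpec, gen_elytron

groups = {}
for pattern, label in (("C", "reticulate"), ("A", "dense")):
    syn = gen_elytron(ElytronSpec.for_pattern(pattern, seed=7))
    areas = measure_cells(syn.cell_mask, syn.spec.scale_px_per_mm)
    n_trans = count_transverse(syn.costa_mask, syn.transect)
    groups[label] = areas
    s = boxplot_stats(areas)
    print(
        f"{label:10s} {syn.spec.n_longitudinal} longitudinal, "
        f"{n_trans} transverse costae; {len(areas)} cells, "
        f"median area {s.median:.3f} mm2 (range {s.minimum:.3f}-{s.maximum:.3f})"
    )

ratio = (sum(groups["reticulate"]) / len(groups["reticulate"])) / (
    sum(groups["dense"]) / len(groups["dense"])
)
print(f"\nmean cell area ratio reticulate/dense = {ratio:.2f}")
print("  -> several-fold larger cells make the net structure visible at a distance")
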