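"""Split a single voxel three ways and compare conservation.

A voxel of -50 HU sits between neighbors at 0 and 100 HU.  Plain linear
and spline interpolation each produce children whose mean drifts away from
the parent; the conserving split picks the closest children whose mean is
the parent exactly.
"""

from ctcompat import (
    alpha_from_neighbors,
    classical_linear_split,
    classical_spline_split,
    delta_measure,
    split_voxel,
)

prev, hu0, nxt = 0.0, -50.0, 100.0

lin = classical_linear_split(prev, hu0, nxt)
spl = classical_spline_split((prev, hu0, nxt))
ct = split_voxel(hu0, alpha_from_neighbors(prev, nxt))

for name, (hu1, hu2) in [("linear", lin), ("spline", spl), ("conserving", (ct.hu1, ct.hu2))]:
    print(
        f"{name:>10}: children = ({hu1:8.3f}, {hu2:8.3f})  "
        f"mean = {(hu1 + hu2) / 2:8.3f}  delta = {delta_measure(hu0, hu1, hu2):6.3f}"
    )

# delta is |mean(children) - parent|: nonzero means the split changed the
# parent's HU (hence mass) estimate; only the conserving split keeps it at 0.
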