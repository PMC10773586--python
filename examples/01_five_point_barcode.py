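"""The five-point planar cloud: Rips filtration by hand-checkable steps.

Builds the packaged fixture, computes its barcode with the in-package
persistence engine and walks the Betti numbers through four scales.
"""

from topoeeg import betti_numbers, five_point_cloud, vr_persistence

cloud = five_point_cloud()
print("points:\n", cloud.points)

barcode = vr_persistence(cloud)
print(f"\nbarcode (eps_max = {barcode.eps_max:.4f}):")
for iv in barcode.intervals:
    print(f"  H{iv.dim}  [{iv.birth:.4f}, {iv.death:.4f})")

for eps in (0.6, 1.0, 1.44, 2.35):
    b0, b1 = betti_numbers(barcode, eps)
    print(f"eps = {eps:<5} components beta0 = {b0}, loops beta1 = {b1}")

# beta0 drops 5 -> 4 -> 3 -> 1 as pairs connect; at eps = 2.35 the five
# points form a single pentagon-shaped loop (beta1 = 1), which fills in
# (dies) once triangles appear at scale 3.
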