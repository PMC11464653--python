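"""Point-count stereology on a synthetic histology class map.

A 100-point grid is overlaid on a generated label image (airspace,
acinar tissue, non-acinar tissue, hemorrhage) and the class under each
intersection is tallied; percentages estimate area fractions.  The
alveolar-tissue percentage subtracts non-acinar points from the overall
tissue count.
"""

from cralekit import stereology as ster
from cralekit.synthetic import HistologyTruth, gen_histology_image

# post-CPR-like composition: airspace partly replaced by tissue/hemorrhage
truth = HistologyTruth(airspace=0.41, acinar_tissue=0.38,
                       nonacinar_tissue=0.08, hemorrhage=0.13)
img, realized = gen_histology_image(512, 512, truth, seed=4)
grid = ster.overlay_grid(512, 512, n_points=100)
res = ster.point_count(img, grid)

print("class        counted   true area")
for cls, frac in realized.as_dict().items():
    print(f"{cls:16s} {res.percentages[cls]:5.1f}%   {100 * frac:5.1f}%")
print(f"alveolar tissue (tissue minus non-acinar): "
      f"{ster.alveolar_tissue_percent(res):.1f}%")
print(f"wet-to-dry ratio 10 g / 2 g = {ster.wet_to_dry(10.0, 2.0):.1f} (edema index)")
print(f"lung/body ratio 548 g / 33 kg = {ster.lung_body_ratio(548.0, 33.0):.1f} g/kg")
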