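"""Find significant stratigraphic zones in a diatom-style assemblage.

Draws a three-zone Dirichlet-multinomial count table, converts it to
relative abundances, and splits it by information content with broken-stick
significance.
"""

from arclake.proxies import relative_abundance
from arclake.synthetic import ZoneScenario, gen_assemblage
from arclake.zonation import recursive_zonation

scenario = ZoneScenario(seed=1)  # 24 samples, true boundaries before samples 8 and 16
matrix = relative_abundance(gen_assemblage(scenario))
result = recursive_zonation(matrix, max_splits=8)

print(f"total information: {result.total_information:.2f} nats, "
      f"{result.n_significant} significant boundary(ies)")
print("\nrank  position  depth_cm  reduction  broken_stick  significant")
for k, s in enumerate(result.splits, 1):
    frac = s.reduction / result.total_information
    print(f"{k:4d}  {s.position:8d}  {s.boundary_depth:8.2f}  "
          f"{frac:9.3f}  {s.broken_stick:12.3f}  {s.significant}")
print(f"\ntrue boundaries were before samples {scenario.boundaries}; a split is "
      "significant while its share of the total information exceeds the "
      "broken-stick expectation for its rank.  Both cuts land on the true "
      "boundaries; the weaker mid-record transition can fall just short of "
      "significance at these count sizes, which is the null model doing its job.")
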