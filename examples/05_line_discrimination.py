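"""Recover a planted cell-line difference from cluster percentage areas.

Simulates 3 ESC-like + 3 iPSC-like cells where the iPSC-like line carries
twice the nucleic-acid abundance, runs the full segmentation, and compares
the DNA-dominated ("red") cluster's percentage area between lines with an
unpaired two-sample t test — the semiquantitative readout used to
discriminate pluripotent stem-cell lines.
"""

import ramancell as rc
from ramancell.preprocessing import (
    estimate_background,
    infer_cell_mask,
    normalize_map,
    split_regions,
    subtract_background,
)

experiment = rc.generate_experiment(n_per_line=3, dna_scale_ipsc=2.0, seed=11)

maps = []
for smap, _ in experiment:
    mask = infer_cell_mask(smap)
    fp = split_regions(smap).fingerprint
    fp = subtract_background(fp, estimate_background(fp, mask))
    fp, _ = normalize_map(fp)
    maps.append(fp)

dataset = rc.pool_maps(maps)
pca = rc.fit_pca(dataset)
km = rc.fit_kmeans(rc.project(dataset, pca, K=6), k=7, seed=0, n_restarts=20)
rc.identify_outside_cluster(km, dataset)
summary = rc.summarize_clusters(km, dataset)

red = next(j for j, color in summary.colors.items() if color == "red")
print("red (DNA-dominated) cluster percentage of in-cell area per map:")
sub = summary.areas[summary.areas["cluster"] == red]
for _, row in sub.iterrows():
    print(f"  {row['map_id']:>16} ({row['line_label']}): {row['percent']:6.2f} %")

g = rc.compare_groups(summary.areas, red)
print(f"{g.group_a}: {g.mean_a:.2f} ± {g.sem_a:.2f} %  vs  "
      f"{g.group_b}: {g.mean_b:.2f} ± {g.sem_b:.2f} %  (mean ± SEM)")
print(f"two-sample t = {g.t_statistic:.2f}, df = {g.df}, p = {g.p_value:.4g}")
# A small p with near-zero red area in the ESC-like maps reproduces the
# hallmark finding: the high-DNA cluster appears almost exclusively in the
# line with elevated nucleic-acid content.
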