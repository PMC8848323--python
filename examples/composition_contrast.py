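"""Macro vs micro window composition at the full desk scale.

Simulates the default scenario (6 x 20-Mb macrochromosomes + 11 x 8-Mb
microchromosomes, 208 Mb) and contrasts per-1-Mb-window GC%, genic fraction
and repeat fraction between classes with two-sided Wilcoxon rank-sum tests.
Takes ~20 s.
"""

import synpaint as sp

assembly, genes, repeats, class_map = sp.composition_scenario(seed=42)
track = sp.build_track(assembly, genes, repeats, class_map)
n = track.df.groupby("chrom_class").size()
print(f"windows: {n.get('macro', 0)} macro, {n.get('micro', 0)} micro\n")

for metric in ("gc_pct", "gene_frac", "repeat_frac"):
    c = sp.compare_macro_micro(track, metric)
    print(f"{metric:12s} macro mean {c.mean_macro:8.4g}  micro mean {c.mean_micro:8.4g}  "
          f"W={c.W:9.0f}  U={c.U:8.0f}  p={c.p_value:.2e}")

print("\nW is the rank-sum of the macro group, U the Mann-Whitney statistic. "
      "Micro windows run higher in GC and genic fraction, macro windows in "
      "repeat coverage — the classic macro/micro compositional contrast.")
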