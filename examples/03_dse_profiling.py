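"""Score downstream sequence elements (DSEs) for U/GU-richness.

CstF-64 requires a U- or GU-rich element downstream of the cleavage
site; Star-PAP targets lack one. The profiler reports U fraction, the
longest U run, the most U-rich 10-nt sub-window and the GU/UG
dinucleotide fraction, and calls each window U_RICH or SUBOPTIMAL.
"""

from collections import Counter

from starpap import (
    AnalysisParams,
    CohortConfig,
    DseCall,
    generate_cohort,
    group_regions,
    profile_dse,
)

cohort = generate_cohort(CohortConfig(seed=7))
regions = group_regions(cohort.sites, cohort.sequences, AnalysisParams())
labels = {t.gene_id: t.label for t in cohort.truth}

calls = Counter()
examples = {}
for gene, rs in regions.items():
    for r in rs:
        p = profile_dse(r.dse_seq)
        calls[(labels[gene], p.call)] += 1
        examples.setdefault(labels[gene], (gene, p))

for label in ("target", "background"):
    gene, p = examples[label]
    print(f"{label} gene {gene}: U fraction {p.u_fraction:.2f}, "
          f"max U run {p.max_u_run}, max 10-nt window U {p.max_window_u:.2f}, "
          f"GU/UG fraction {p.gu_dinucleotide_fraction:.2f} -> {p.call.value}")

n_t = calls[("target", DseCall.SUBOPTIMAL)] + calls[("target", DseCall.U_RICH)]
n_b = calls[("background", DseCall.SUBOPTIMAL)] + calls[("background", DseCall.U_RICH)]
print(f"\ntarget DSEs called SUBOPTIMAL: "
      f"{calls[('target', DseCall.SUBOPTIMAL)]}/{n_t}")
print(f"background DSEs called U_RICH: "
      f"{calls[('background', DseCall.U_RICH)]}/{n_b}")
# A SUBOPTIMAL call predicts that CstF-64 cannot load, excluding the
# canonical poly(A) polymerase from the site.
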