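"""Walk one wild-type site through the in-silico reporter mutant series.

Starting from a synthetic Star-PAP-type site (AUA-core motif upstream,
suboptimal DSE downstream), apply the two reporter edits - AUA -> GGG
in the upstream element and a UUUUUU substitution in the DSE - singly
and combined, and classify each variant. The four variants cover the
full four-state model of poly(A) polymerase selection.
"""

from starpap import CohortConfig, Label, generate_cohort, run_analysis
from starpap.classify import classify_archetypes, make_archetypes

cohort = generate_cohort(CohortConfig(seed=7))
result = run_analysis(cohort.sequences, cohort.sites, cohort.fold_changes)

truth = {t.gene_id: t for t in cohort.truth}
wt_call = next(c for c in result.site_calls
               if c.label is Label.STAR_PAP and truth[c.gene_id].embedded)
region = result.target_regions[wt_call.gene_id][0]
print(f"wild-type site: {wt_call.gene_id} "
      f"(motif {wt_call.motif_word} at {wt_call.motif_distance} nt)")

calls = classify_archetypes(make_archetypes(region), result.frequent_words)
print(f"\n{'variant':8} {'USE motif':>9} {'DSE call':>11} {'predicted PAP':>14}")
for name in ("WT", "U-Mut", "D-Mut", "DU-Mut"):
    c = calls[name]
    print(f"{name:8} {str(c.motif_present):>9} {c.dse_call.value:>11} "
          f"{c.label.value:>14}")
# STAR_PAP: exclusively non-canonical processing; BOTH: redundant;
# PAP_ALPHA: canonical; NONE: no modelled polymerase engages the site.
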