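"""Cohort statistics on a synthetic healthy-aging / Hakim's disease cohort.

Simulates the four-group cohort (three healthy age bands + Hakim-like
patients) with published-summary means and SDs, then runs the comparison
battery: Kruskal-Wallis across age bands, Mann-Whitney for Hakim vs.
elderly, and a Pearson correlation with Fisher-z 95% CI.
"""

from csfoi import stats, synthetic

cohort = synthetic.simulate_cohort(synthetic.default_cohort_config(seed=11))
wide = cohort.pivot_table(index="subject_id", columns="measurement",
                          values="value")
groups = cohort[["subject_id", "group"]].drop_duplicates().set_index("subject_id")

by_group = {
    g: wide.loc[groups["group"] == g, "evans_index"].to_numpy()
    for g in ("under40", "40to59", "over60", "hakim")
}

h, p_kw = stats.group_compare(
    {g: by_group[g] for g in ("under40", "40to59", "over60")}, "kruskal_wallis"
)
print(f"Evans index across healthy age bands: Kruskal-Wallis H = {h:.2f}, "
      f"p = {p_kw:.3g}")

u, p_mw = stats.group_compare(
    {"over60": by_group["over60"], "hakim": by_group["hakim"]}, "mann_whitney"
)
print(f"Evans index, Hakim vs healthy >=60:   Mann-Whitney U = {u:.0f}, "
      f"p = {p_mw:.3g}")

res = stats.pearson_with_ci(wide["evans_index"], wide["ventricle_volume_ml"])
print(f"Evans index vs ventricular volume:    r = {res.r:.2f} "
      f"(95% CI {res.ci_low:.2f} to {res.ci_high:.2f}, n = {res.n})")

print("\nHakim's disease shows a markedly higher Evans index (ventricular"
      "\nenlargement) than healthy elderly; the Fisher-z interval quantifies"
      "\nhow precisely the morphometric association is estimated.")
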