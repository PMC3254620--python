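"""Place a fossil foot among extant primate groups by pedal proportions.

Computes the six inter-element indices for the packaged fossil foot,
compares them with the published extant group summaries, and runs a
jackknifed discriminant analysis on a synthetic nine-group training set.
"""

from unguis import foot, tables
from unguis.records import DFA_GROUPS, FootRecord, GroupSummary
from unguis.simulate import FootGroupSpec, gen_foot_dataset

fossil = FootRecord(individual_id="AMNH 143612/143640",
                    **tables.table_foot_elements().to_dict())
ratios = foot.compute_ratios(fossil)
print("fossil pedal indices:")
for name in ("pp4_mt4", "mt1_mt2", "mt3_mt4", "mt4_mt5", "pp2_pp5", "pp3_pp4"):
    print(f"  {name:8s} = {getattr(ratios, name):.3f}")

print("\nnearest extant group per proximal-phalanx index "
      "(single-specimen t, published summaries, n = 25 assumed per group):")
pps = tables.phalanx_ratio_summaries()
for ratio in ("pp2_pp5", "pp3_pp4"):
    sub = pps[pps.ratio == ratio]
    summaries = [GroupSummary(r.group, ratio, r.mean, r.variance, 25)
                 for r in sub.itertuples()]
    out = foot.fossil_vs_groups(getattr(ratios, ratio), summaries, m=2)
    print(f"  {ratio}: nearest = {out['nearest']}")

print("\njackknifed discriminant analysis on a synthetic 9-group training set:")
specs = [FootGroupSpec(group=g, dfa_group=g, n=12,
                       ratio_means={"pp4_mt4": 0.45 + 0.07 * i,
                                    "mt1_mt2": 1.0 - 0.05 * i,
                                    "pp2_pp5": 0.7 + 0.04 * i},
                       ratio_variances={"pp4_mt4": 0.0006, "mt1_mt2": 0.0006,
                                        "pp2_pp5": 0.0006})
         for i, g in enumerate(DFA_GROUPS)]
train = gen_foot_dataset(specs, seed=0)
cv = foot.loo_cv(train)
print(f"  leave-one-out success rate: {cv.success_rate:.1%} "
      f"({cv.n_refits} refits)")
model = foot.lda_fit(train)
group, post = foot.lda_classify(model, fossil)
print(f"  fossil assigned to {group} with posterior {post.max():.2f}")
print("\nHigh jackknife success means the standardized element lengths carry")
print("strong group signal; the fossil's posterior says which synthetic group")
print("profile its proportions resemble most.")
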