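"""A miniature Monte-Carlo power study (a thin slice of the full grid).

Runs 100 replications per condition for bias condition 2 at high strength,
at medium trait SD (SD_b = 2), crossing two sample sizes with two re-test
frequencies, and prints chi-square rejection rates with the 80%-power
verdicts.  Power grows in both n and t; the full 405-condition grid is the
same loop at scale (see the `ildbench grid` command).
"""

from ildbench import GridConfig, SimCondition, aggregate, build_grid, run_condition

cfg = GridConfig(n=(50, 100), t=(10, 30), sd_b=(2.0,), bias=(2,),
                 strength=("high",), replications=100, root_seed=1)
summaries = [run_condition(c, cfg.replications, cfg.design)
             for c in build_grid(cfg)]

print("bias 2 (items 5+6), high strength, SD_b = 2:")
print(f"{'n':>4} {'t':>4} {'chi2 rej.':>10} {'mean CFI':>9} {'verdict':>12}")
for s in summaries:
    rate = s.rejection_rate("chi2_p<0.05")
    verdict = "adequate" if rate >= 0.80 else "underpowered"
    print(f"{s.condition.n:>4} {s.condition.t:>4} {rate:>10.2f} "
          f"{s.index_mean['cfi']:>9.3f} {verdict:>12}")

rec = aggregate(summaries)["recommendations"]
chi = rec[rec["criterion"] == "chi2_p<0.05"]
print(f"\n{int((chi['verdict'] == 'adequate').sum())} of {len(chi)} cells "
      "reach 80% power on the chi-square test.")
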