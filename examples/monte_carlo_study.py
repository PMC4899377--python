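"""A small seeded Monte-Carlo study of ML estimator quality.

Draws repeated BBX samples at the study's true parameters
(alpha, beta, lam, theta) = (0.5, 0.2, 0.5, 8), refits the 4-parameter
model on each, and reports per-parameter bias and RMSE.  Bias should
shrink as n grows; RMSE always dominates |bias| by definition.  The run
here is scaled down (reps=100) so it finishes in about a minute; raise
``reps`` for smoother numbers.
"""

import betaburrx as bb

design = bb.MCDesign(
    true_params=bb.BBXParams(0.5, 0.2, 0.5, 8),
    n_list=(100, 1000),
    reps=100,
    seed=42,
)
report = bb.run_mc_study(design)

print(f"{'n':>6} {'parameter':<10} {'bias':>12} {'rmse':>12} {'converged':>10}")
for row in report.rows():
    print(f"{row['n']:>6} {row['parameter']:<10} {row['bias']:>12.4g} "
          f"{row['rmse']:>12.4g} {row['n_converged']:>10}")
print("\nNote: at n=100 the 4-parameter likelihood has a nearly flat ridge in")
print("(alpha, theta), so a few replicates wander far and inflate bias/RMSE;")
print("the shrinkage from n=100 to n=1000 is the meaningful signal.")
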