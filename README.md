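# famnet — family mental-health symptom networks

`famnet` implements a complete analysis pipeline for studying how
mental-health symptoms relate *within family triads* (child, mother,
father), for epidemiologists and psychometricians working with cohort
panel data:

1. **Cross-sectional networks.** A Gaussian graphical model over 9
   subscale nodes — child internalising/externalising/prosocial (SDQ)
   and each parent's emotional symptoms / social dysfunction / loss of
   confidence (GHQ-12) — estimated by nodewise lasso regressions
   combined with the AND rule.  Edge weights are on the
   partial-correlation scale: `pcor(i,j) = −K_ij / √(K_ii K_jj)` for
   precision matrix `K`.
2. **Bridge centrality.** Edges connecting nodes of *different* family
   members are bridge edges; per node, bridge strength
   `Σ_u |w(v,u)|` over other members' nodes and bridge betweenness
   (fractional count of cross-member shortest paths through the node,
   distances `1/|w|`).
3. **Stability and comparison.** Case-dropping bootstrap summarized by
   the correlation-stability (CS) coefficient (largest drop proportion
   keeping the subsample/full correlation above 0.70 with 95%
   probability; > 0.25 = acceptable), and a permutation network
   comparison test (NCT) of bridge-edge differences `E = |w₁ − w₂|`
   between subgroups with Bonferroni–Holm correction.
4. **Longitudinal networks.** A random-intercept panel graphical VAR
   over 13 emotional-symptom item nodes:

   ```
   y_ft = μ + b_f + x_ft,   b_f ~ N(0, K_between⁻¹)
   x_ft = B x_{f,t−1} + ζ_ft,   ζ_ft ~ N(0, K_within⁻¹)
   ```

   estimated by full-information maximum likelihood (FIML) under
   arbitrary wave-level missingness, with the saturated → pruned
   (recursive Wald pruning at p < 0.05) → step-up (modification-index
   search accepted while BIC improves) model-selection protocol and
   RMSEA / CFI fit indices.

Because cohort microdata of this kind are access-restricted, the
package ships a first-class synthetic-data module
(`famnet.synthetic_data`) that generates family triads from known
ground-truth networks (PD precision matrices; stationary VAR
coefficients), so every estimator has a parameter-recovery test
surface.

## Worked example

```python
import numpy as np
from famnet import (family_triad_truth, simulate_cross_sectional,
                    fit_nodewise_lasso)
from famnet.bridge import bridge_centrality_table

truth = family_triad_truth()          # 9-node triad network, known pcors
data = simulate_cross_sectional(truth, n=8795, seed=20260919)
fit = fit_nodewise_lasso(data, seed=20260919)
print(len(fit.network.edge_list()))   # 15  (= number of true edges)
print(np.abs(fit.network.weights - truth.partial_correlations).max())
# 0.0244
tab = bridge_centrality_table(fit.network)
print(tab.sort_values("bridge_strength", ascending=False).iloc[0])
# node m_emo, community mother, bridge_strength 0.387
```

The estimated network recovers the generating support exactly at this
sample size; all edge weights are within 0.025 of the true partial
correlations; and the node with the highest bridge strength is the
mother's emotional-symptom node — the structural feature the default
truth plants.

The `analysis/` directory holds the numbered end-to-end drivers
(simulate the cohort, fit the cross-sectional network, stability,
subgroup NCT, panel GVAR); each writes its tables under `results/`.
A `famnet` CLI exposes the same stages
(`famnet simulate|fit-ggm|bridge|stability|nct|fit-panel`).

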