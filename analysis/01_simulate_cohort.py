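"""Generate the synthetic study cohort.

Two arms, mirroring the real study's design at its sample sizes:

* cross-sectional: 8795 family triads, 9 subscale nodes (child
  internalising / externalising / prosocial; each parent's emotional
  symptoms / social dysfunction / loss of confidence), drawn from a
  known ground-truth partial-correlation network with mother-child and
  mother-father bridges and no independent father-child edge;
* longitudinal: 3757 families, 13 emotional-symptom item nodes over up
  to 13 waves with 25% wave-level attrition, driven by a stationary
  graphical VAR around family random intercepts with a planted
  mother-overwhelmed -> child-worry -> child-nervous ->
  mother-overwhelmed temporal loop.

Writes results/data/ (CSV panels plus the JSON ground truth) so later
scripts can score their estimates against the generating networks.
"""

import json
from pathlib import Path

import numpy as np

from famnet.synthetic_data import (
    FamilyPanelSpec, family_triad_truth, make_gvar_truth,
    simulate_cross_sectional, simulate_panel,
)
from famnet.io import write_panel

SEED = 20260919
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

LOOP = [("m_overwhelmed", "c_worry", 0.1), ("c_worry", "c_nervous", 0.1),
        ("c_nervous", "m_overwhelmed", 0.1)]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    truth = family_triad_truth()
    data = simulate_cross_sectional(truth, 8795, seed=SEED)
    # subgroup covariates are assigned independently of symptoms: the
    # generator's subgroups share one truth unless configured otherwise
    data["child_sex"] = rng.choice(["girl", "boy"], size=len(data))
    data["child_age"] = rng.integers(4, 16, size=len(data))
    data["income"] = np.round(rng.lognormal(8.1, 0.5, size=len(data)), 2)
    data.to_csv(OUT / "cross_sectional.csv", index=False)
    (OUT / "cross_sectional_truth.json").write_text(json.dumps({
        "node_names": truth.node_names,
        "communities": truth.communities,
        "partial_correlations": truth.partial_correlations.round(6).tolist(),
    }, indent=2))
    print(f"cross-sectional arm: {len(data)} families, "
          f"{len(truth.node_names)} nodes -> {OUT/'cross_sectional.csv'}")

    gtruth = make_gvar_truth(cross_member_paths=LOOP)
    spec = FamilyPanelSpec(n_families=3757, n_waves=13,
                           missing_wave_rate=0.25, seed=SEED + 1)
    panel = simulate_panel(gtruth, spec)
    write_panel(panel, OUT / "panel.csv")
    (OUT / "panel_truth.json").write_text(json.dumps({
        "node_names": gtruth.node_names,
        "mu": gtruth.mu.tolist(),
        "B": gtruth.B.round(6).tolist(),
        "sigma_zeta": gtruth.sigma_zeta.round(6).tolist(),
        "sigma_between": gtruth.sigma_between.round(6).tolist(),
    }, indent=2))
    n_flag = len(panel.low_wave_families)
    print(f"longitudinal arm: {spec.n_families} families x "
          f"{spec.n_waves} waves (25% attrition; {n_flag} families "
          f"with <2 waves flagged) -> {OUT/'panel.csv'}")


if __name__ == "__main__":
    main()
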