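"""Fit the cross-sectional family network and its bridge centrality.

Estimates the 9-node regularized partial-correlation network (nodewise
lasso, AND rule) on the synthetic cohort, extracts bridge edges (edges
connecting different family members), and computes bridge strength and
bridge betweenness per node.  Scores the estimate against the
generating truth.  Writes results/cross_sectional/.
"""

import json
from pathlib import Path

import numpy as np

from famnet.bridge import bridge_centrality_table, bridge_edges
from famnet.ggm import fit_nodewise_lasso

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260919
NODES = ["c_int", "c_ext", "c_pro", "m_emo", "m_sd", "m_lc",
         "f_emo", "f_sd", "f_lc"]


def main():
    out = ROOT / "cross_sectional"
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    data = pd.read_csv(ROOT / "data" / "cross_sectional.csv")[NODES]
    truth = json.loads((ROOT / "data" / "cross_sectional_truth.json").read_text())
    pcor_true = np.array(truth["partial_correlations"])

    fit = fit_nodewise_lasso(data, seed=SEED)
    edges = fit.network.edge_list()
    edges.to_csv(out / "edges.csv", index=False)

    btable, _ = bridge_edges(fit.network)
    btable.to_csv(out / "bridge_edges.csv", index=False)
    cent = bridge_centrality_table(fit.network)
    cent.to_csv(out / "bridge_centrality.csv", index=False)

    W = fit.network.weights
    support_ok = bool(np.array_equal(W != 0, pcor_true != 0))
    max_err = float(np.abs(W - pcor_true).max())
    top = cent.sort_values("bridge_strength", ascending=False).iloc[0]

    print(f"estimated network: {len(edges)} edges, {len(btable)} bridge edges")
    print(f"support matches generating truth: {support_ok}; "
          f"max |w_hat - pcor| = {max_err:.4f}")
    print(f"highest bridge strength: {top['node']} "
          f"({top['community']}, {top['bridge_strength']:.3f}) — the default "
          f"truth plants its strongest bridges on maternal emotional symptoms")
    (out / "summary.json").write_text(json.dumps({
        "n_edges": int(len(edges)), "n_bridge_edges": int(len(btable)),
        "support_recovered": support_ok, "max_weight_error": max_err,
        "top_bridge_strength_node": str(top["node"]),
    }, indent=2))


if __name__ == "__main__":
    main()
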