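"""Generate every synthetic input table used by the downstream analyses.

Writes a planted kinome screen (Kd matrix + sensitivities), a batch of
dose-response surfaces with known Bliss excess, a kinase expression
profile, and the demo signaling network to results/inputs/.
"""

import json
from pathlib import Path

from polysynergy import io, synthetic

SEED = 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    screen = synthetic.gen_screen(n_drugs=41, n_kinases=385, n_essential=3,
                                  sigma=0.05, seed=SEED)
    io.write_results(screen.kd, OUT / "kd.csv")
    io.write_results(screen.sensitivity, OUT / "dss.csv")
    (OUT / "planted_targets.json").write_text(
        json.dumps(sorted(screen.planted)) + "\n")
    print(f"screen: {len(screen.kd.drugs)} drugs x {len(screen.kd.kinases)} "
          f"kinases, planted essential targets {sorted(screen.planted)}")

    deltas = {"synergy_strong": 8.0, "synergy_mild": 4.0, "additive": 0.0,
              "antagonism": -5.0}
    for i, (name, delta) in enumerate(deltas.items()):
        s = synthetic.gen_surface(delta=delta, sigma=3.0, seed=SEED + 100 + i)
        io.write_results(s.matrix, OUT / f"surface_{name}.csv")
    print(f"surfaces: {len(deltas)} matrices with planted excess {deltas}")

    expr = synthetic.gen_expression(screen.kd.kinases, seed=SEED + 1)
    io.write_results(expr, OUT / "expression.csv")

    net, targets = synthetic.gen_network("aurkb_zak_csf1r_demo")
    io.write_results(net, OUT / "network.sif")
    (OUT / "network_targets.json").write_text(json.dumps(targets) + "\n")
    print(f"network: {len(net.edges)} signed edges over {len(targets)} genes")


if __name__ == "__main__":
    main()
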