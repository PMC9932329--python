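"""Average linear subsystem shares of the carrying capacity, 2007-2019.

Finding: the human-activity subsystem dominates at 45% on average; the
economic-contribution and ecological-services subsystems account for 28%
and 27%.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ecohealth import CarryingAssessment, Subsystem, load_fixture_shandong
from ecohealth.state_space import subsystem_shares

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fx = load_fixture_shandong()
    moduli = pd.DataFrame(
        {
            "ecc_economic": fx.subsystem_moduli["economic"],
            "ecc_ecological": fx.subsystem_moduli["ecological"],
            "ecc_human": fx.subsystem_moduli["human"],
        }
    )
    moduli["ecc"] = np.sqrt((moduli**2).sum(axis=1))
    ideal = {
        "ecc_economic": fx.subsystem_ideals[Subsystem.ECONOMIC],
        "ecc_ecological": fx.subsystem_ideals[Subsystem.ECOLOGICAL],
        "ecc_human": fx.subsystem_ideals[Subsystem.HUMAN],
        "ecc": fx.ecc_star,
    }
    shares = subsystem_shares(CarryingAssessment(moduli=moduli, ideal=ideal))
    out = {sub.value: round(pct, 2) for sub, pct in shares.items()}
    OUT.mkdir(exist_ok=True)
    (OUT / "subsystem_shares.json").write_text(json.dumps(out, indent=2) + "\n")
    for sub, pct in shares.items():
        print(f"{sub.value:<12} {pct:5.2f}%  (rounds to {round(pct)}%)")


if __name__ == "__main__":
    main()
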