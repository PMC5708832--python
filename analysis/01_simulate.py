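"""Generate the default synthetic monitoring dataset.

Nine survey sites (downstream to upstream), 1996-2013, with the stated
world: mean YOY density 1.96/m (annual CV 46%, spatial CV 28%), 77% YOY,
3-pass depletion at capture probability 0.5, sinusoidal 13+/-7 C water
temperatures, food availability declining in the four downstream sites,
captive release sizes rising over time, and adults forward-simulated from
the size-conditional life-cycle truth (q3, q4) = (1.178, 0.594).

Writes the four observable tables and the generating truth under
results/synthetic/.
"""

import sys
from pathlib import Path

import numpy as np

from condsmolt.io import save_scenario_config
from condsmolt.synthetic_data import ScenarioConfig, generate_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(seed: int = 1) -> None:
    cfg = ScenarioConfig(seed=seed)
    ds = generate_scenario(cfg)
    ds.write(OUT)
    save_scenario_config(cfg, OUT / "scenario.yaml")
    adults = ds.annual["adults"].to_numpy()
    print(f"wrote {len(ds.survey)} survey rows for {len(cfg.sites)} sites x "
          f"{len(cfg.years)} years -> {OUT}")
    print(f"adult counts: first 5 years {np.round(adults[:5])}, "
          f"last 5 years {np.round(adults[-5:])}")
    print("the late-period decline is driven by the configured downstream "
          "food-availability decline acting through size-conditional smolting")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
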