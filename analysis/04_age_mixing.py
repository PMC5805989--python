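"""Age-mixing matrices per wave and their epidemic-growth implications.

Computes, for each wave, the participant-age × contact-age ratio matrix
relative to proportionate mixing with 1000-resample bootstrap CIs, the
touch-only stratification, and the next-generation growth ranking of the
waves.  Writes results/mixing.csv, mixing_touch.csv, ngm_ranking.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from contactdiaries.io_model import WAVES, read_census, read_diary_panel
from contactdiaries.mixing import bootstrap_ci, contact_rate_matrix, ngm_growth_rank

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    panel = read_diary_panel(ROOT / "data")
    census = read_census(ROOT / "data" / "census.csv")
    waves = [w for w in WAVES if w in set(panel.diaries["wave"])]

    for touch_only, path in ((False, "mixing.csv"), (True, "mixing_touch.csv")):
        tables = []
        for w in waves:
            m = bootstrap_ci(panel, census, w, touch_only=touch_only,
                             n_boot=1000, seed=SEED)
            tables.append(m.to_frame())
            if not touch_only:
                own = {"5-19": "6-19", "20-39": "20-39", "40-64": "40-64", "65+": "65+"}
                diag = {pg: round(float(m.ratio.loc[pg, cg]), 2) for pg, cg in own.items()}
                print(f"{w}: own-age mixing ratios {diag}")
        pd.concat(tables).to_csv(ROOT / path, index=False)

    ranking = ngm_growth_rank({w: contact_rate_matrix(panel, w) for w in waves})
    ranking.to_csv(ROOT / "ngm_ranking.csv", index=False)
    print("epidemic growth ranking (dominant eigenvalue of per-capita "
          "contact-rate matrix):")
    print(ranking.round(2).to_string(index=False))
    print(f"wrote mixing tables and ranking to {ROOT}")


if __name__ == "__main__":
    main()
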