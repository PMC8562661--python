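"""Merge the simulated streams and tabulate quality per resolution shell.

Reads the streams written by 02_simulate_datasets.py, applies per-pattern
scaling and Monte-Carlo merging, and writes the full quality-metric shell
tables (completeness, redundancy, SNR, R_split, CC_1/2, CC*, CC_ano) to
results/shell_stats_<arm>.csv plus overall numbers to
results/merging_overall.json.
"""

import json
from pathlib import Path

from pinksfx import merging, streamio, truth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
OUT = ROOT / "results"


def main() -> None:
    sf = truth.read_structure_factors(SCRATCH / "ground_truth.hkl")
    overall = {}
    for arm in ("sase-6keV", "pink-6keV"):
        ds = streamio.read_stream(SCRATCH / f"{arm}.stream")
        obs = merging.scale_patterns(ds.observations())
        mg = merging.merge(obs, ds.cell, ds.symmetry)
        table = merging.shell_table(mg, 10, d_max=24.8, d_min=ds.d_min, sf=sf)
        table.to_csv(OUT / f"shell_stats_{arm}.csv", index=False)
        overall[arm] = {
            "n_patterns": ds.n_patterns,
            "n_unique": len(mg),
            "r_split_pct": merging.r_split(mg),
            "cc_half": merging.cc_half(mg),
            "cc_star": merging.cc_star(merging.cc_half(mg)),
            "cc_ano": merging.cc_ano(mg),
            "cc_anoref": merging.cc_anoref(mg, sf),
            "snr": merging.snr(mg),
            "redundancy": merging.redundancy(mg),
            "completeness_pct": merging.completeness(mg, 24.8, ds.d_min),
        }
        print(arm, json.dumps(overall[arm], indent=2))
    with open(OUT / "merging_overall.json", "w") as fh:
        json.dump(overall, fh, indent=2)


if __name__ == "__main__":
    main()
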