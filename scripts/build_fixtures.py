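"""Regenerate the packaged synthetic data fixtures.

Writes the Retand RT query FASTA, the 62-sequence model RT panel FASTA and the
toy domain-profile JSON under src/prare/data/.  Deterministic; run from the
repository root after changing the panel builders:

    python scripts/build_fixtures.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from prare.io import GenomeRecord, package_data_path, write_fasta
from prare.panels import PANEL_SEED, build_panels, build_profile_consensi
from prare.profiles import calibrate_profile_threshold


def main():
    queries, panel = build_panels(PANEL_SEED)
    write_fasta(
        [GenomeRecord(h, s) for h, s in queries],
        package_data_path("retand_rt_queries.synthetic.faa"),
    )
    write_fasta(
        [GenomeRecord(h, s) for h, s in panel],
        package_data_path("model_rt_panel.synthetic.faa"),
    )

    consensi = build_profile_consensi(PANEL_SEED)
    profiles = []
    for i, (name, consensus) in enumerate(sorted(consensi.items())):
        thr = calibrate_profile_threshold(consensus, rng_seed=PANEL_SEED + 100 + i)
        profiles.append({"name": name, "consensus": consensus, "threshold": thr})
    with open(package_data_path("domain_profiles.synthetic.json"), "w") as fh:
        json.dump(profiles, fh, indent=1)
    print(f"wrote {len(queries)} queries, {len(panel)} panel seqs, {len(profiles)} profiles")


if __name__ == "__main__":
    main()
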