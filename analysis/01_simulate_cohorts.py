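#!/usr/bin/env python
"""Simulate the two-phase study data at published shape.

Generates the discovery cohort (10 cases / 10 controls, 50% hormone use,
754 miRNAs in technical duplicate) and the replication cohort (54 cases /
108 controls, 78% hormone use) with the default planted truth, and writes
sample sheets, the Ct matrix and the simulation truth under results/data/.
The replication MFI panel is produced later (02) once the discovery phase
has chosen its candidates.
"""

import argparse
from pathlib import Path

from mirdiscover.cohort import write_sample_sheet
from mirdiscover.config import RunConfig
from mirdiscover.simulate import simulate_cohort, simulate_ct_matrix, write_ct_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(seed=args.seed)
    (args.out / "config.yaml").write_text(cfg.to_yaml())
    seeds = cfg.sub_seeds()
    s = cfg.simulation
    truth = s.truth()
    (args.out / "truth.json").write_text(truth.to_json())

    disc = simulate_cohort(s.n_cases_discovery, s.control_ratio_discovery,
                           s.hormone_fraction_discovery, s.age_range,
                           seed=seeds["discovery_cohort"], phase="discovery")
    write_sample_sheet(disc, args.out / "discovery_samples.csv")
    ct = simulate_ct_matrix(disc, truth, n_mirnas=s.n_mirnas,
                            seed=seeds["discovery_ct"])
    write_ct_tsv(ct, args.out / "discovery_ct.tsv")

    rep = simulate_cohort(s.n_cases_replication, s.control_ratio_replication,
                          s.hormone_fraction_replication, s.age_range,
                          seed=seeds["replication_cohort"], phase="replication")
    write_sample_sheet(rep, args.out / "replication_samples.csv")

    print(f"discovery cohort: {len(disc)} samples "
          f"({len(disc.case_ids)} cases), Ct matrix {ct.values.shape}")
    print(f"replication cohort: {len(rep)} samples ({len(rep.case_ids)} cases)")
    print(f"planted truth: {len(truth.effects)} effects, "
          f"{len(truth.reference_mirnas)} references -> {args.out}")


if __name__ == "__main__":
    main()
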