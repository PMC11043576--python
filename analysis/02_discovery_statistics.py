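#!/usr/bin/env python
"""Discovery-phase statistics on the simulated qPCR matrix.

Collapses duplicates, applies the Ct > 34 QC rule, flags outliers, imputes,
globally normalizes, picks five Normfinder references, and selects candidate
miRNAs by stratified t-tests under the dual-threshold rule.  Writes the
candidate table (the Table-2 analogue), the reference list, and the final
replication probe panel; then simulates the replication-phase MFI matrix for
that panel.
"""

import argparse
import json
import warnings
from pathlib import Path

from mirdiscover import discovery as disc
from mirdiscover.cohort import read_sample_sheet
from mirdiscover.config import RunConfig
from mirdiscover.simulate import (
    SimulationTruth,
    read_ct_tsv,
    recovery_report,
    simulate_mfi_matrix,
    write_mfi_tsv,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig.load(args.data / "config.yaml")
    d = cfg.discovery
    seeds = cfg.sub_seeds()
    cohort = read_sample_sheet(args.data / "discovery_samples.csv",
                               phase="discovery")
    truth = SimulationTruth.from_json((args.data / "truth.json").read_text())
    ct = read_ct_tsv(args.data / "discovery_ct.tsv")

    collapsed = disc.collapse_duplicates(ct, d.max_duplicate_discordance)
    filtered, qc = disc.qc_filter(collapsed, d.ct_max, d.max_missing_fraction)
    print(f"QC: censored {qc.n_values_censored} measurements above "
          f"{d.ct_max} cycles, dropped {len(qc.dropped_mirnas)} miRNAs")
    flagged, n_out = disc.flag_outliers(filtered, cohort, d.outlier_alpha)
    print(f"outlier flagging excluded {n_out} values")
    imputed = disc.impute_missing(flagged, cohort, d.impute_strategy)
    expr = disc.global_normalize(imputed)

    groups = {s: cohort.record(s).group for s in imputed.values.columns}
    ranking = disc.normfinder_stability(expr, groups)
    refs = disc.select_references(ranking, d.k_references)
    expr = expr.with_references(refs)
    print(f"Normfinder references: {', '.join(refs)}")

    selection = disc.stratified_ttests(expr, cohort, p_strict=d.p_strict,
                                       p_both=d.p_both, welch=d.welch)
    table = selection.table
    table.to_csv(args.out / "discovery_candidates.tsv", sep="\t",
                 index_label="mirna_id")
    selected = selection.selected_ids
    rec = recovery_report(selected, truth)
    print(f"selected {len(selected)} candidate miRNAs "
          f"(planted recall {rec.recall:.2f}, {rec.n_false} false)")

    s = cfg.simulation
    literature = [f"lit-miR-{i:02d}" for i in range(1, s.n_literature_probes + 1)]
    pos = [f"pos-ctl-{i}" for i in range(1, s.n_positive_controls + 1)]
    neg = [f"neg-ctl-{i}" for i in range(1, s.n_negative_controls + 1)]
    panel = disc.assemble_panel(selected, literature, pos, neg)
    panel.to_csv(args.out / "replication_panel.tsv", sep="\t", index=False)
    print(f"replication panel: {len(panel)} probes")

    rep_cohort = read_sample_sheet(args.data / "replication_samples.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mfi = simulate_mfi_matrix(rep_cohort, truth, panel["probe_id"].tolist(),
                                  blank_wells=s.blank_wells,
                                  qc_fraction=s.qc_fraction,
                                  seed=seeds["replication_mfi"])
    write_mfi_tsv(mfi, args.data / "replication_mfi.tsv")
    (args.out / "discovery_qc.json").write_text(json.dumps({
        "censored_values": qc.n_values_censored,
        "dropped_mirnas": list(qc.dropped_mirnas),
        "outliers_excluded": n_out,
        "references": list(refs),
        "n_selected": len(selected),
        "planted_recall": rec.recall,
        "false_selections": rec.n_false,
    }, indent=2))


if __name__ == "__main__":
    main()
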