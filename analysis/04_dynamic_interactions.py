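#!/usr/bin/env python
"""Proximity and half-weight association indices for gated dyads.

Re-derives the period-clipped trajectories from the telemetry, applies the
home-range VI > 0.1 gate from the overlap step, and computes Prox plus HAI
over the landfill and waste-cell polygons for every qualifying dyad-period,
with the per-cohort mean +/- SD summary.
"""

from pathlib import Path

import pandas as pd

from sounderspace import interaction, overlap, pipeline, tracks

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trajs = tracks.read_tracks(ROOT / "data" / "telemetry.csv")
    polygons = tracks.read_polygons(ROOT / "data" / "polygons.geojson")
    cfg = pipeline.merge_config({})

    period_trajs = {}
    for tr in trajs:
        for scale in cfg["scales"]:
            for period, sub in tracks.partition_periods(
                tr, scale, min_fixes=int(cfg["min_fixes"])
            ):
                period_trajs[(tr.animal_id, scale, period.label)] = sub

    rec_df = pd.read_csv(ROOT / "tables" / "overlap_records.csv")
    records = [
        overlap.OverlapRecord(
            overlap.Dyad(r.animal_a, r.animal_b), r.scale, str(r.period),
            r.ud_level, r.overlap_2d_ab, r.overlap_2d_ba, r.vi,
        )
        for r in rec_df.itertuples()
    ]
    dyads = sorted(
        {(r.dyad.animal_a, r.dyad.animal_b) for r in records}
    )
    irecords = interaction.compute_interactions(
        [overlap.Dyad(a, b) for a, b in dyads], records, period_trajs,
        polygons,
    )
    tables = ROOT / "tables"
    interaction.interaction_records_frame(irecords).to_csv(
        tables / "interaction_records.csv", index=False
    )
    cohort_of = {t.animal_id: t.cohort_year for t in trajs}
    summary = interaction.summarize_interactions(irecords, cohort_of)
    summary.to_csv(tables / "interaction_summary.csv", index=False)
    print(f"{len(irecords)} gated dyad-periods")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
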