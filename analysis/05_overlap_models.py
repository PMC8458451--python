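#!/usr/bin/env python
"""Beta-regression model selection for the overlap responses.

Builds the covariate table (distance to waste cells, percent of UD in the
landfill and habitat polygons, sow attributes, period weather, UD level and
year), fits the candidate beta-regression sets per scale and response,
ranks them by AICc, and reports odds ratios with 90% confidence intervals
for each top model.
"""

from pathlib import Path

import pandas as pd

from sounderspace import pipeline, tracks

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    uds = pipeline.load_uds(ROOT / "cache" / "uds.npz")
    trajs = tracks.read_tracks(ROOT / "data" / "telemetry.csv")
    polygons = tracks.read_polygons(ROOT / "data" / "polygons.geojson")
    attributes = tracks.read_attributes(ROOT / "data" / "attributes.csv")
    weather = pd.read_csv(ROOT / "data" / "weather.csv")
    cfg = pipeline.merge_config({})

    aggregates = pd.read_csv(ROOT / "tables" / "sow_overlap_aggregates.csv")
    animal_cohort = {t.animal_id: t.cohort_year for t in trajs}
    selections, ors, merged = pipeline.stage_models(
        uds, aggregates, polygons, attributes, weather, animal_cohort, cfg
    )
    tables = ROOT / "tables"
    merged.to_csv(tables / "model_table.csv", index=False)
    frames = []
    for (scale, response), df in sorted(selections.items()):
        df = df.copy()
        df.insert(0, "scale", scale)
        df.insert(1, "response", response)
        frames.append(df)
    sel = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    sel.to_csv(tables / "model_selection.csv", index=False)
    oframes = []
    for (scale, response), df in sorted(ors.items()):
        df = df.copy()
        df.insert(0, "scale", scale)
        df.insert(1, "response", response)
        oframes.append(df)
    odf = pd.concat(oframes, ignore_index=True) if oframes else pd.DataFrame()
    odf.to_csv(tables / "odds_ratios.csv", index=False)

    for (scale, response), df in sorted(selections.items()):
        top = df.iloc[0]
        print(f"{scale}/{response}: top model {top.formula} "
              f"(AICc {top.aicc:.1f}, {int(df.plausible.sum())} plausible)")
    print(f"wrote model tables under {tables}")


if __name__ == "__main__":
    main()
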