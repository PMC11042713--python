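#!/usr/bin/env python
"""Composition of the consolidated 662-item diet dataset.

Tallies the packaged observation table by method, food group within the
direct observations, and vertebrate subcategory — the table-form equivalent
of the study's composition figure — and writes them under results/.
"""

from pathlib import Path

from jaydiet.diet_compilation import tally
from jaydiet.fixtures import study_observations

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    ROOT.mkdir(exist_ok=True)
    df = study_observations()
    by_method = tally(df, ["method"])
    by_method.to_csv(ROOT / "tally_by_method.tsv", sep="\t", index=False)
    print("items by observation method (n = %d):" % len(df))
    print(by_method.to_string(index=False))

    do = df[df["method"] == "DO"]
    do_groups = tally(do, ["food_group"])
    do_groups.to_csv(ROOT / "tally_do_food_groups.tsv", sep="\t",
                     index=False)
    print("\ndirect observations by food group:")
    print(do_groups.to_string(index=False))

    vert = do[(do["food_group"] == "V") & (do["subcategory"] != "")]
    vert_sub = tally(vert, ["subcategory"])
    vert_sub.to_csv(ROOT / "tally_do_vertebrate_subcategories.tsv",
                    sep="\t", index=False)
    print("\nvertebrate direct observations by subcategory:")
    print(vert_sub.to_string(index=False))

    season = tally(df[df["method"] == "SC"], ["season", "food_group"])
    season.to_csv(ROOT / "tally_stomach_by_season.tsv", sep="\t",
                  index=False)
    print("\nstomach-content items by season and food group:")
    print(season.to_string(index=False))


if __name__ == "__main__":
    main()
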