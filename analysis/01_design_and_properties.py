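"""Build the factorial stimulus set and verify property independence.

Constructs the 120-image design (10 objects x 2 manipulations x 6
scale-consistency levels), assigns the four ordinal property levels,
and checks that scale consistency is decoupled from the nuisance
properties via Spearman rank correlations.  Writes the image table and
the correlation matrices to results/.
"""

from pathlib import Path

from scenescale import check_property_independence, make_scale_factors
from scenescale.pipeline import build_design

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    images, _ = build_design()
    images.to_csv(OUT / "stimulus_images.tsv", sep="\t", index=False)

    corr, pvals = check_property_independence(images)
    corr.to_csv(OUT / "property_spearman_r.tsv", sep="\t")
    pvals.to_csv(OUT / "property_spearman_p.tsv", sep="\t")

    print(f"scale factors: {make_scale_factors()}")
    print(f"{len(images)} images; per scale level:")
    print(images.groupby("scale_level").size().to_string())
    print("\nSpearman correlations between property levels:")
    print(corr.round(4).to_string())
    r_rw = corr.loc["scale_consistency", "real_world_size"]
    print(
        f"\nscale consistency vs real-world size r = {r_rw:.4f} "
        "(structurally zero: every object contributes all six levels)"
    )


if __name__ == "__main__":
    main()
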