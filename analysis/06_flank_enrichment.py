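"""Annotation enrichment in the 50-kb flanks of the query regions.

Draws matched controls (chromosome, size, CpG density) from the candidate
pool, then tests each annotation class in 1-kb windows out to 50 kb with
Fisher's exact test and BH adjustment across the whole profile.
"""

from __future__ import annotations

from common import RESULTS, STUDY, load_fixtures

from corsivkit import enrichment, io


def main() -> None:
    fx = load_fixtures()
    controls = enrichment.matched_controls(fx["regions"], fx["pool"],
                                           seed=STUDY.seed)
    io.write_regions(controls, RESULTS / "matched_controls.bed")

    profile = enrichment.window_enrichment(fx["regions"], controls,
                                           fx["annotations"])
    profile.to_csv(RESULTS / "enrichment_profile.tsv", sep="\t", index=False)
    for cls, grp in profile.groupby("cls"):
        sig = grp[grp["significant"]]
        if sig.empty:
            print(f"{cls}: no significant windows")
            continue
        print(f"{cls}: {len(sig)} significant windows, offsets "
              f"{int(sig['offset_kb'].min())}-{int(sig['offset_kb'].max())} kb, "
              f"median OR {sig['odds_ratio'].median():.2f}")


if __name__ == "__main__":
    main()
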