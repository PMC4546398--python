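#!/usr/bin/env python
"""Clean the raw tag table: poly-A artifact removal, then singleton removal.

Mirrors the pre-processing applied to SuperSAGE libraries before any
statistics; most raw tag species are sequencing-error singletons and
disappear here, while nearly all counted mass survives.
"""

from pathlib import Path

from dualsage import TagCountTable, clean_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = TagCountTable.from_tsv(RESULTS / "sim" / "counts_raw.tsv")
    mass_in = int(table.counts[["count_ctl", "count_inf"]].sum().sum())
    cleaned, report = clean_table(table)
    mass_out = int(cleaned.counts[["count_ctl", "count_inf"]].sum().sum())

    cleaned.to_tsv(RESULTS / "counts_clean.tsv")
    print(f"input tag species: {report['input_tags']:,}")
    print(f"removed poly-A artifacts: {report['removed_polya']:,}")
    print(f"removed singletons: {report['removed_singletons']:,}")
    print(f"kept {report['output_tags']:,} tag species "
          f"({100 * mass_out / mass_in:.2f}% of counted tags)")


if __name__ == "__main__":
    main()
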