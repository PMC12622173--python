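#!/usr/bin/env python
"""Filter low-signal peaks and call differential tag-count signal.

Applies the shipped thresholds (max tag count >= 4 to keep a peak; a call
requires fold change > 2 and BH-adjusted p < 0.05) and writes the
differential table plus up/down peak BEDs under results/analysis/diff/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regnet import diffpeaks, intervals as iv

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    counts = iv.read_counts_tsv(BASE / "inputs" / "counts.tsv")
    groups = dict(
        line.split("\t")
        for line in (BASE / "inputs" / "groups.tsv").read_text().splitlines()
        if line.strip()
    )
    peaks = iv.read_bed(BASE / "inputs" / "peaks.bed")
    thr = diffpeaks.Thresholds()
    retained = diffpeaks.filter_low_signal(counts, thr)
    result = diffpeaks.differential_test(retained, groups, thr)
    out = BASE / "diff"
    out.mkdir(parents=True, exist_ok=True)
    result.to_csv(out / "differential.tsv", sep="\t")
    up = list(result.index[result["call"] == "up_in_b"])
    down = list(result.index[result["call"] == "down_in_b"])
    iv.write_bed(peaks.subset(up), out / "up.bed")
    iv.write_bed(peaks.subset(down), out / "down.bed")
    print(f"retained {len(retained)}/{len(counts)} peaks after the tag-count filter")
    print(f"differential calls at FC>2, padj<0.05: {len(up)} up, {len(down)} down")
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
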