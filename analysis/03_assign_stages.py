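"""Assign each DE gene to its stage of peak upregulation.

Genes meeting the DE criteria in at least one contrast are assigned to the
stage with the largest log2FC versus iPSC; genes with no positive contrast
fall back to the iPSC baseline.
"""

import argparse
from pathlib import Path

from isletdiff import assign_stages, io, stage_set
from isletdiff.stages import DEFAULT_STAGES


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--de", type=Path, default=Path("results/de_table.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/assignments.tsv"))
    args = ap.parse_args()

    table = io.read_table(args.de)
    asn = assign_stages(table)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    io.write_table(asn, args.out)

    print(f"{int(asn['qualifying'].sum())} qualifying DE genes; "
          "per-stage counts:")
    for stage in DEFAULT_STAGES:
        print(f"  {stage:>5}: {len(stage_set(asn, stage))}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
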