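#!/usr/bin/env python
"""Step 3 — score the comparison against the planted truth.

Re-runs the comparison in memory on the step-1 bundle and measures
parameter recovery: PAV recall/precision at +/-100 bp breakpoints, SNP
recall/precision inside one-to-one blocks, SV classification per type
and coverage of the planted SNP-enriched blocks.
"""

import argparse
import json
from pathlib import Path

from paircomp.pipeline import evaluate_run, run_compare
from paircomp.simulate import read_truth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/evaluation.json"))
    args = ap.parse_args()

    truth = read_truth(args.sim / "truth")
    result = run_compare(args.sim / "genome_a.fasta",
                         args.sim / "genome_b.fasta")
    metrics = evaluate_run(result, truth)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(metrics, indent=2, sort_keys=True,
                                   default=str) + "\n")
    print(f"wrote {args.out}")
    for side in ("A", "B"):
        m = metrics[f"pav_{side}"]
        print(f"  PAV {side}: recall {m['recall']:.3f} "
              f"precision {m['precision']:.3f} "
              f"({m['n_called']}/{m['n_planted']} called/planted)")
    m = metrics["snp"]
    print(f"  SNP: recall {m['recall']:.4f} precision {m['precision']:.4f}")
    for t, d in metrics["sv"]["per_type"].items():
        print(f"  SV {t}: {d['recovered']}/{d['planted']} recovered")
    print(f"  enrichment overlap: min "
          f"{metrics['enrichment']['min_overlap']:.3f}")


if __name__ == "__main__":
    main()
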