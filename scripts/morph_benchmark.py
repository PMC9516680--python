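"""Run the manifest-driven morphing benchmark on deposited structures.

Usage: python scripts/morph_benchmark.py [--manifest data/benchmarks/manifest.yaml]

Each case morphs a loop of the source structure toward the target
conformation along closure-preserving constrained modes and reports the
initial and final backbone RMSD.  Structures must be fetched first with
scripts/fetch_benchmarks.py (network required).
"""

import argparse
import sys
from pathlib import Path

import yaml

from loopmodes import LoopSpec, MorphOptions, morph_to_target, read_structure, select_loop


def run_case(case, bench_dir: Path):
    source = read_structure(bench_dir / case["source"])
    target = read_structure(bench_dir / case["target"])
    first, last = case["loop"]
    spec = LoopSpec(case["chain"], int(first), int(last))
    loop = select_loop(source, spec, env_cutoff=10.0)
    return morph_to_target(loop, target, MorphOptions())


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--manifest",
        default=Path(__file__).resolve().parent.parent
        / "data" / "benchmarks" / "manifest.yaml",
    )
    args = ap.parse_args()
    manifest_path = Path(args.manifest)
    bench_dir = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    failures = 0
    print(f"{'case':28s} {'initial':>8s} {'final':>8s} {'bound':>6s}")
    for case in manifest["cases"]:
        missing = [
            f for f in (case["source"], case["target"])
            if not (bench_dir / f).exists()
        ]
        if missing:
            print(f"{case['name']:28s} MISSING {missing} "
                  "(run scripts/fetch_benchmarks.py)")
            failures += 1
            continue
        res = run_case(case, bench_dir)
        ok = res.final_rmsd <= case["max_final_rmsd"]
        print(
            f"{case['name']:28s} {res.initial_rmsd:8.2f} {res.final_rmsd:8.2f}"
            f" {case['max_final_rmsd']:6.2f} {'ok' if ok else 'FAIL'}"
        )
        failures += not ok
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
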