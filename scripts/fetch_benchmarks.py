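"""Download the worked-example benchmark structures from the PDB.

Usage: python scripts/fetch_benchmarks.py

Requires network access to files.rcsb.org; writes the PDB files next to
data/benchmarks/manifest.yaml.
"""

import sys
import urllib.request
from pathlib import Path

import yaml

BENCH_DIR = Path(__file__).resolve().parent.parent / "data" / "benchmarks"


def main() -> int:
    manifest = yaml.safe_load((BENCH_DIR / "manifest.yaml").read_text())
    files = set()
    for case in manifest["cases"]:
        files.add(case["source"])
        files.add(case["target"])
    for name in sorted(files):
        dest = BENCH_DIR / name
        if dest.exists():
            print(f"{name}: already present")
            continue
        url = f"https://files.rcsb.org/download/{Path(name).stem.upper()}.pdb"
        print(f"fetching {url}")
        try:
            urllib.request.urlretrieve(url, dest)
        except OSError as exc:
            print(f"FAILED: {exc}", file=sys.stderr)
            return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
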