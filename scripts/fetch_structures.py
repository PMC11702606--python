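#!/usr/bin/env python
"""Download the deposited crystal structures used by the published-value
tests (PDB 9MIN: designed mini TCR-mimic complex; 3HAE: 3M4E5 Fab;
2BNQ: 1G4 TCR) into tests/data/structures/. Requires network access;
the files are not redistributed with the package.

    python scripts/fetch_structures.py [--dest tests/data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ENTRIES = ("9min", "3hae", "2bnq")
URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest", type=Path,
        default=Path(__file__).resolve().parent.parent
        / "tests" / "data" / "structures",
    )
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    status = 0
    for pdb_id in ENTRIES:
        target = args.dest / f"{pdb_id}.cif"
        if target.is_file():
            print(f"{target} already present")
            continue
        url = URL.format(pdb_id=pdb_id.upper())
        try:
            print(f"fetching {url} ...")
            with urllib.request.urlopen(url, timeout=60) as resp:
                target.write_bytes(resp.read())
            print(f"wrote {target}")
        except Exception as exc:  # noqa: BLE001 - report and continue
            print(f"failed to fetch {pdb_id}: {exc}", file=sys.stderr)
            status = 1
    return status


if __name__ == "__main__":
    raise SystemExit(main())
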