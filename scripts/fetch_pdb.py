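#!/usr/bin/env python
"""Fetch the deposited structures used by the literature-value checks.

Downloads 7pkw (the two-domain VirB8-like ectodomain, one monomer per
asymmetric unit), 8s7l (its A204C-A264C double-cysteine variant, trimer in
the asymmetric unit) and 3ub1 (TcpC, two trimers) from the PDB into
``data/pdb/``.  Requires internet access; the test-suite checks that use
these files fail with a pointer to this script when they are absent.
"""

import sys
import urllib.request
from pathlib import Path

CODES = ("7pkw", "8s7l", "3ub1")
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "pdb"


def main() -> int:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    status = 0
    for code in CODES:
        dest = OUT_DIR / f"{code}.pdb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        try:
            print(f"fetching {url} ...")
            with urllib.request.urlopen(url, timeout=60) as response:
                dest.write_bytes(response.read())
        except OSError as exc:
            print(f"  failed: {exc}")
            status = 1
    return status


if __name__ == "__main__":
    sys.exit(main())
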