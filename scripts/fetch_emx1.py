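"""Fetch the human Emx1 example sequences (requires network access).

Downloads the NM_004097.2 mRNA GenBank record from NCBI, splits its CDS at
the annotated exon boundaries, and writes the per-exon CDS segments
(expected lengths 898, 185 and 1105 bp) to data/emx1_cds_exons.fa, where
the Emx1 acceptance test looks for them:

    python scripts/fetch_emx1.py
"""

import os
import sys
import urllib.request

ACCESSION = "NM_004097.2"
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    f"?db=nuccore&id={ACCESSION}&rettype=gb&retmode=text"
)
OUT = os.path.join(os.path.dirname(__file__), "..", "data", "emx1_cds_exons.fa")


def main():
    from Bio import SeqIO  # deferred so --help works without Biopython

    print(f"fetching {ACCESSION} from NCBI ...")
    with urllib.request.urlopen(URL, timeout=60) as resp:
        text = resp.read().decode()
    tmp = OUT + ".gb"
    os.makedirs(os.path.dirname(OUT), exist_ok=True)
    with open(tmp, "w") as fh:
        fh.write(text)
    record = SeqIO.read(tmp, "genbank")
    os.remove(tmp)

    cds = [f for f in record.features if f.type == "CDS"]
    exons = [f for f in record.features if f.type == "exon"]
    if len(cds) != 1 or not exons:
        sys.exit("unexpected feature layout in the GenBank record")
    cds_start = int(cds[0].location.start)
    cds_end = int(cds[0].location.end)

    segments = []
    for exon in exons:
        lo = max(int(exon.location.start), cds_start)
        hi = min(int(exon.location.end), cds_end)
        if lo < hi:
            segments.append(str(record.seq[lo:hi]).upper())
    lengths = [len(s) for s in segments]
    print(f"CDS exon segment lengths: {lengths}")
    if lengths != [898, 185, 1105]:
        print(
            "warning: lengths differ from the published 898/185/1105 bp "
            "example; the annotation may have changed"
        )
    with open(OUT, "w") as fh:
        for i, seg in enumerate(segments, start=1):
            fh.write(f">hEMX1_exon{i}\n")
            for j in range(0, len(seg), 70):
                fh.write(seg[j : j + 70] + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
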