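"""The 19 multi-read distant-fusion rows, encoded from their printed
chromosome/strand/distance columns (section, samples(reads), donor gene,
5' chrom+strand, 3' chrom+strand, distance or None)."""

TABLE2_ROWS = [
    # Long distance (> 200,000 bp, same chrom/strand, acceptor downstream)
    ("long_range", {"HBR": 2}, "IQCJ-SCHIP1", "+3", "+3", 501_759),
    ("long_range", {"N3": 1, "T2": 5, "T3": 15}, "TMPRSS2-ERG", "-21", "-21", 3_062_463),
    # Scrambled exons (acceptor upstream of donor)
    ("scrambled", {"UHR": 2}, "RPS6KB1-TMEM49", "+17", "+17", 74_936),
    ("scrambled", {"UHR": 2}, "GCN1L1-MSI1", "-12", "-12", 157_217),
    # Inversions (opposite strands of one chromosome)
    ("inversion", {"UHR": 7}, "GAS6-RASA3", "+13", "-13", 185_397),
    ("inversion", {"UHR": 2}, "TGOLN2-USP39", "-2", "+2", 320_033),
    ("inversion", {"UHR": 4}, "ARFGEF2-SULF2", "+20", "-20", 1_172_861),
    ("inversion", {"UHR": 2}, "LITAF-DECR2", "-16", "+16", 11_193_286),
    ("inversion", {"N1": 2}, "REV1-CPSF3", "-2", "+2", 89_944_295),
    # Translocations (different chromosomes)
    ("translocation", {"UHR": 4}, "BCAS4-BCAS3", "+20", "+17", None),
    ("translocation", {"UHR": 3}, "BCR-ABL1", "+22", "+9", None),
    ("translocation", {"N1": 2}, "CAMTA1-SPPL3", "+1", "-12", None),
    ("translocation", {"UHR": 2}, "DYNC1H1-EIF4B", "+14", "+12", None),
    ("translocation", {"T3": 2}, "MBTPS1-SERF2", "-16", "+15", None),
    ("translocation", {"N2": 2}, "OGT-RBM22", "+X", "-5", None),
    ("translocation", {"N1": 2}, "ROR2-USP36", "-9", "-17", None),
    ("translocation", {"T3": 2}, "SEC31A-C6orf62", "-4", "-6", None),
    ("translocation", {"UHR": 2}, "TIMM9-PRKDC", "-14", "-8", None),
    ("translocation", {"N1": 2}, "ZDHHC8-UBL5", "+22", "+19", None),
]


def encode_row(section, samples, name, cs5, cs3, distance):
    """Build split-alignment records realizing the printed geometry.

    Donor position is placed arbitrarily; the acceptor position follows the
    printed distance and the section's orientation (downstream for long
    distance, upstream for scrambled).  One record per supporting read.
    """
    from ticfinder.splice_classifier import Segment, SplitAlignmentRecord

    strand5, chrom5 = cs5[0], "chr" + cs5[1:]
    strand3, chrom3 = cs3[0], "chr" + cs3[1:]
    donor_pos = 5_000_000
    if distance is None:
        acceptor_pos = 7_000_000
    elif section == "scrambled":
        # acceptor upstream of the donor in transcription orientation
        acceptor_pos = (
            donor_pos - distance if strand5 == "+" else donor_pos + distance
        )
    else:
        acceptor_pos = (
            donor_pos + distance if strand5 == "+" else donor_pos - distance
        )
    anchor = 20
    if strand5 == "+":
        seg_a = Segment(chrom5, strand5, donor_pos - anchor, donor_pos)
    else:
        seg_a = Segment(chrom5, strand5, donor_pos, donor_pos + anchor)
    if strand3 == "+":
        seg_b = Segment(chrom3, strand3, acceptor_pos, acceptor_pos + anchor)
    else:
        seg_b = Segment(chrom3, strand3, acceptor_pos - anchor, acceptor_pos)
    records = []
    i = 0
    for sample, n in sorted(samples.items()):
        for _ in range(n):
            records.append(
                SplitAlignmentRecord(
                    read_id=f"{name}_{i}", sample_id=sample,
                    segment_a=seg_a, segment_b=seg_b,
                )
            )
            i += 1
    return records
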