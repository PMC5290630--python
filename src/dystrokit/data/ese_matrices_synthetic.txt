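# Synthetic SR-protein ESE position weight matrices.
# Layout follows the classic four-SR-protein set (motif widths 7/8/7/6 with
# per-matrix calling thresholds), but both the weights and the thresholds are
# synthetic stand-ins, NOT measured binding data: each matrix is shaped
# around an arbitrary consensus, with its threshold placed about one score
# unit below the consensus maximum so that called sites exist and strong
# single-base hits can disrupt them.  Replace with a real matrix file of the
# same format for production scoring.
#
# Format: blank-line-separated blocks of
#   NAME <id> / THRESHOLD <float> / WIDTH <int> / A|C|G|T <WIDTH scores>

NAME SRSF1_synthetic
THRESHOLD 3.5
WIDTH 7
A -0.4 0.65 -0.3 0.55 -0.45 -0.2 0.6
C 0.7 -0.35 0.6 -0.25 0.65 -0.5 -0.3
G -0.15 -0.55 -0.45 -0.4 -0.2 0.75 -0.35
T -0.6 -0.25 -0.15 -0.6 -0.3 -0.45 -0.55

NAME SRSF2_synthetic
THRESHOLD 4.0
WIDTH 8
A -0.45 -0.3 -0.5 -0.2 -0.35 -0.55 -0.25 -0.4
C -0.2 -0.5 0.65 0.55 -0.45 0.7 -0.3 -0.15
G 0.6 0.75 -0.35 -0.45 -0.25 -0.4 -0.5 0.55
T -0.35 -0.15 -0.25 -0.6 0.6 -0.2 0.65 -0.45

NAME SRp40_synthetic
THRESHOLD 3.45
WIDTH 7
A 0.55 -0.4 0.7 -0.3 0.6 -0.45 -0.2
C -0.25 0.65 -0.35 0.75 -0.4 -0.15 0.55
G -0.45 -0.2 -0.55 -0.45 -0.25 0.65 -0.4
T -0.6 -0.5 -0.15 -0.55 -0.5 -0.6 -0.45

NAME SRp55_synthetic
THRESHOLD 3.0
WIDTH 6
A -0.35 -0.45 -0.25 -0.55 -0.3 -0.4
C -0.5 -0.2 0.7 -0.3 -0.45 0.6
G -0.25 0.65 -0.4 0.75 -0.2 -0.25
T 0.6 -0.3 -0.5 -0.15 0.65 -0.5
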