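{
  "provenance": "Invariant pairs (det1, det2) computed symbolically from Alexander polynomials: torus knots 3_1, 5_1 from the closed form (t^pq - 1)(t - 1)/((t^p - 1)(t^q - 1)); 4_1, 5_2, 6_1, 6_2, 6_3 from their standard coefficient lists (4_1: t^2-3t+1, 5_2: 2t^2-3t+2, 6_1: 2t^2-5t+2, 6_2: t^4-3t^3+3t^2-3t+1, 6_3: t^4-3t^3+5t^2-3t+1). det1 = |Delta(-1)|; det2 = odd part of |Delta(-2)| (the +-t^k normalisation ambiguity at t = -2 is a power of two, so the odd part is the minimal positive integer invariant). All eight pairs are distinct; in particular (det1, det2) separates 4_1 = (5, 11) from 5_1 = (5, 31), which det1 alone cannot.",
  "table": {
    "0_1": [1, 1],
    "3_1": [3, 7],
    "4_1": [5, 11],
    "5_1": [5, 31],
    "5_2": [7, 1],
    "6_1": [9, 5],
    "6_2": [11, 59],
    "6_3": [13, 67]
  }
}
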