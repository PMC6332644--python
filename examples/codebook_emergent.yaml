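# Emergent (remodelled) codification protocol: after the inductive pass
# the a-priori columns are replaced by four — legitimisation, reduction of
# uncertainty, symbolic paper (role), resistance — with "political support"
# and "political will" among the resistance codes.  Match patterns are
# ILLUSTRATIVE keyword cues, as in codebook_a_priori.yaml.
version: emergent-v2
columns:
  - name: Legitimisation
    codes:
      - name: Institutional legitimacy
        patterns:
          - regex: "legitima|institutional"
      - name: Normative endorsement
        patterns:
          - regex: "guideline|standard|declaration"
  - name: Reduction of uncertainty
    codes:
      - name: Risk management
        patterns:
          - regex: "risk|uncertaint"
      - name: Simulation
        patterns:
          - regex: "simulat|appearance"
  - name: Symbolic paper
    codes:
      - name: Moral authority
        patterns:
          - regex: "moral|bioethic"
      - name: Control mechanism
        patterns:
          - regex: "social control|oversight"
  - name: Resistance
    codes:
      - name: Political support
        patterns:
          - literal: political support
          - regex: "politic.*support"
      - name: Political will
        patterns:
          - literal: political will
      - name: Institutional actors
        patterns:
          - regex: "stakeholder|actor"
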