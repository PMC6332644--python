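# A-priori codification protocol: six analytic category columns for the
# role of institutional bioethics committees in public health policy.
# The category columns and code names follow the published protocol; the
# match patterns are ILLUSTRATIVE keyword cues chosen for demonstration —
# any real study must calibrate them against its own corpus.
version: a-priori-v1
columns:
  - name: Forms of institutionalisation
    codes:
      - name: Normative or advisory committees
        patterns:
          - regex: "advisory (committee|bod(y|ies))"
          - literal: national commission
      - name: Committees of professional medical associations
        patterns:
          - literal: medical association
          - literal: professional society
      - name: Committees of care and hospital ethics
        patterns:
          - regex: "hospital ethics|clinical ethics committee"
      - name: Committees of ethics in research
        patterns:
          - regex: "research ethics|institutional review board|ethics committees, research"
  - name: Forms of governance
    codes:
      - name: Governance mechanisms
        patterns:
          - literal: governance
          - literal: regulation
      - name: Universal declaration references
        patterns:
          - literal: universal declaration
          - literal: unesco
  - name: Institutional structure
    codes:
      - name: Consultant entity
        patterns:
          - regex: "consult(ant|ation|ative)"
      - name: Regulatory entity
        patterns:
          - regex: "regulator|oversight"
      - name: Collective decision processes
        patterns:
          - literal: decision making
          - literal: deliberation
  - name: Political discourse
    codes:
      - name: Medical-scientific field
        patterns:
          - regex: "medical|scientific"
      - name: Public-social field
        patterns:
          - regex: "public health|social"
      - name: Political field
        patterns:
          - regex: "politic"
  - name: Mechanism power
    codes:
      - name: Knowledge-power-truth
        patterns:
          - regex: "knowledge|expertise|authority"
      - name: Regulatory practices
        patterns:
          - regex: "legislat|jurisprudence|legal"
      - name: Power over populations
        patterns:
          - regex: "population|biopolit"
  - name: Symbolic role
    codes:
      - name: Government elites
        patterns:
          - regex: "government|federal"
      - name: Power elite
        patterns:
          - literal: elite
      - name: Control mechanism
        patterns:
          - regex: "social control|control mechanism"
      - name: Intellectual and moral authority
        patterns:
          - regex: "moral|bioethic"
      - name: Discussion forums
        patterns:
          - regex: "forum|participation|community"
      - name: Passive actors
        patterns:
          - literal: passive
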