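# demo instrument: a compact six-sub-tool example for worked examples and docs.
# Sub-tool 3 standard 3.1 carries the published criterion weights (3,3,4,4,4,4,4).
schema_version: 1
name: demo
version: "1.0"
max_weight: 5
subtools:
  - index: 1
    dimension_name: Infrastructure and equipment of the health facility
    method: checklist
    respondent_rule:
      dispensary: [1, 1]
      health_center: [1, 1]
      hospital_opd: [1, 1]
    standards:
      - id: "1.1"
        question: Does the facility offer a clean and supportive physical environment?
        criteria:
          - id: "1.1a"
            text: The facility has a functioning water source.
            weight: 3
          - id: "1.1b"
            text: The waiting area is clean and shaded.
            weight: 2
          - id: "1.1c"
            text: Sharps are disposed of in puncture-proof containers.
            weight: 5
  - index: 2
    dimension_name: Job expectations
    method: interview_plus_checklist
    respondent_rule:
      dispensary: [1, 3]
      health_center: [3, 10]
      hospital_opd: [10, 10]
    standards:
      - id: "2.1"
        question: Do providers know what is expected from them in terms of service delivery?
        criteria:
          - id: "2.1a"
            text: The provider has a written job description available.
            weight: 2
          - id: "2.1b"
            text: The provider can name the services offered at the facility.
            weight: 2
  - index: 3
    dimension_name: Knowledge, skills and ethics of healthcare providers
    method: direct_observation
    respondent_rule:
      dispensary: [1, 3]
      health_center: [3, 10]
      hospital_opd: [10, 10]
    standards:
      - id: "3.1"
        question: Does the provider adhere to principles of clinical history and physical examination?
        criteria:
          - id: "3.1a"
            text: The provider greets the client.
            weight: 3
          - id: "3.1b"
            text: The provider sees the client in privacy.
            weight: 3
          - id: "3.1c"
            text: The provider recognizes and addresses non-verbal communication from the client.
            weight: 4
          - id: "3.1d"
            text: The provider asks open ended questions during history taking.
            weight: 4
          - id: "3.1e"
            text: The provider gives the client the opportunity to ask questions, listens and responds.
            weight: 4
          - id: "3.1f"
            text: The provider performs physical examination systematically as per individual case requirement.
            weight: 4
          - id: "3.1g"
            text: The provider requests/performs investigations required and gives clear explanations to the client concerning the purpose of tests and the procedures.
            weight: 4
      - id: "3.2"
        question: Does the provider manage scenario-specific consultations correctly?
        criteria:
          - id: "3.2a"
            text: The provider assesses danger signs in a child under five (IMCI).
            weight: 4
            scenario: under5_imci
          - id: "3.2b"
            text: The provider performs the required antenatal examinations.
            weight: 4
            scenario: pregnant
          - id: "3.2c"
            text: The provider requests a malaria test for a fever patient over five.
            weight: 4
            scenario: fever_over5
          - id: "3.2d"
            text: The provider screens a TB/HIV suspect according to guidelines.
            weight: 4
            scenario: tb_hiv
  - index: 4
    dimension_name: Health facility management and administration
    method: checklist
    respondent_rule:
      dispensary: [1, 1]
      health_center: [1, 1]
      hospital_opd: [1, 1]
    standards:
      - id: "4.1"
        question: Does the facility have a sound management system?
        criteria:
          - id: "4.1a"
            text: Essential medicines from the council list are in stock.
            weight: 5
          - id: "4.1b"
            text: Monthly reports were submitted on time.
            weight: 3
          - id: "4.1c"
            text: Minutes of the last facility meeting are on file.
            weight: 2
  - index: 5
    dimension_name: Staff motivation
    method: structured_interview
    respondent_rule:
      dispensary: [1, 3]
      health_center: [5, 10]
      hospital_opd: [5, 10]
    standards:
      - id: "5.1"
        question: Are providers motivated to fulfil job expectations?
        criteria:
          - id: "5.1a"
            text: The provider received salary on time in the last three months.
            weight: 3
          - id: "5.1b"
            text: The provider attended a training in the last year.
            weight: 3
          - id: "5.1c"
            text: In-house education sessions take place regularly.
            weight: 2
  - index: 6
    dimension_name: Clients' satisfaction
    method: exit_interview
    respondent_rule:
      dispensary: [5, 10]
      health_center: [5, 10]
      hospital_opd: [5, 10]
    standards:
      - id: "6.1"
        question: Are community expectations of health service performance met?
        criteria:
          - id: "6.1a"
            text: The client was seen in privacy.
            weight: 4
          - id: "6.1b"
            text: The client received explanations about the diagnosis and treatment.
            weight: 4
          - id: "6.1c"
            text: The client had the opportunity to ask questions.
            weight: 4
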