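# Attribute schema of the reference telephone survey (Taiwan, n = 3074,
# respondents aged 15+): demographic variables plus computer ownership and
# internet access.  Category order matches the printed tables; "Don't
# know/no answer" and "Other" are ordinary categories, never missing data.
attributes:
  - name: gender
    prefix: G
    categories: [Male, Female]
  - name: age_band
    prefix: A
    categories: [15-24, 25-34, 35-44, 45-54, 55-64, ">=65"]
  - name: education
    prefix: E
    categories:
      - Below primary school
      - Junior high school
      - Senior high school
      - Junior college
      - University
      - Graduate and above
  - name: marital_status
    prefix: M
    categories: [Single, Married or cohabiting, Other]
  - name: geographic_area
    prefix: L
    categories:
      - Northern Area
      - Central Area
      - Southern Area
      - Eastern Area
      - Taipei City
      - Kaohsiung City
  - name: personal_income_band
    prefix: P
    categories:
      - "<=450"
      - 451-650
      - 651-950
      - 951-1250
      - 1251-1550
      - 1551-2250
      - ">=2251"
      - Don't know/no answer
  - name: family_income_band
    prefix: F
    categories:
      - No income or unstable
      - "<=650"
      - 651-1250
      - 1251-1850
      - 1851-2450
      - 2451-3050
      - 3051-4650
      - ">=4651"
      - Don't know/no answer
  - name: computer_ownership
    prefix: C
    categories: ["Yes", "No"]
  - name: internet_access
    prefix: I
    categories: ["Yes", "No"]
services: [dms, dhcs]
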