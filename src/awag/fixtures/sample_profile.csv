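variable,item_id,label,n,pct
total,T,Total,3074,100.0
gender,G1,Male,1518,49.38
gender,G2,Female,1556,50.62
age_band,A1,15-24,509,16.6
age_band,A2,25-34,621,20.2
age_band,A3,35-44,568,18.5
age_band,A4,45-54,565,18.4
age_band,A5,55-64,367,11.9
age_band,A6,>=65,444,14.4
education,E1,Below primary school,384,12.5
education,E2,Junior high school,249,8.1
education,E3,Senior high school,1014,32.99
education,E4,Junior college,434,14.1
education,E5,University,847,27.6
education,E6,Graduate and above,146,4.8
marital_status,M1,Single,1065,34.65
marital_status,M2,Married or cohabiting,1876,61.03
marital_status,M3,Other,133,4.3
geographic_area,L1,Northern Area,974,31.7
geographic_area,L2,Central Area,753,24.5
geographic_area,L3,Southern Area,663,21.6
geographic_area,L4,Eastern Area,87,3.0
geographic_area,L5,Taipei City,365,11.9
geographic_area,L6,Kaohsiung City,232,7.5
personal_income_band,P1,<=450,651,21.2
personal_income_band,P2,451-650,211,6.9
personal_income_band,P3,651-950,501,16.3
personal_income_band,P4,951-1250,433,14.1
personal_income_band,P5,1251-1550,279,9.1
personal_income_band,P6,1551-2250,219,7.1
personal_income_band,P7,>=2251,140,4.6
personal_income_band,P8,Don't know/no answer,641,20.8
family_income_band,F1,No income or unstable,104,3.4
family_income_band,F2,<=650,156,5.1
family_income_band,F3,651-1250,478,15.5
family_income_band,F4,1251-1850,561,18.3
family_income_band,F5,1851-2450,445,14.5
family_income_band,F6,2451-3050,316,10.3
family_income_band,F7,3051-4650,295,9.6
family_income_band,F8,>=4651,155,5.0
family_income_band,F9,Don't know/no answer,563,18.3
computer_ownership,C1,Yes,2787,90.66
computer_ownership,C2,No,286,9.3
internet_access,I1,Yes,2154,70.07
internet_access,I2,No,919,29.9
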