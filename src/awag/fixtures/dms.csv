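service,variable,item_id,label,n,aware_count,aware_pct,want_count,want_pct,adopt_count,adopt_pct,gap_pct,region_code
dms,total,T,Total,3074,2667,86.8,2390,77.8,1370,44.6,42.7,O_Wb
dms,gender,G1,Male,1518,1323,87.1,1179,77.7,649,42.8,44.9,O_Wb
dms,gender,G2,Female,1556,1344,86.4,1211,77.9,721,46.3,40.5,O_Wb
dms,age_band,A1,15-24,509,402,78.9,399,78.4,189,37.0,52.8,O_G
dms,age_band,A2,25-34,621,579,93.2,524,84.4,343,55.2,34.5,O_Wb
dms,age_band,A3,35-44,568,539,94.9,470,82.8,282,49.6,40.1,O_Wb
dms,age_band,A4,45-54,565,510,90.3,454,80.3,245,43.3,46.0,O_Wb
dms,age_band,A5,55-64,367,321,87.5,280,76.4,143,39.0,49.0,O_Wb
dms,age_band,A6,>=65,444,315,71.1,263,59.3,169,38.0,35.9,O_G
dms,education,E1,Below primary school,384,257,66.9,221,57.7,124,32.4,43.8,O_G
dms,education,E2,Junior high school,249,187,75.1,174,69.7,72,29.0,58.4,O_G
dms,education,E3,Senior high school,1014,886,87.5,764,75.4,385,38.0,49.6,O_Wb
dms,education,E4,Junior college,434,410,94.5,372,85.9,223,51.4,40.1,O_S
dms,education,E5,University,847,784,92.6,720,84.9,469,55.3,34.9,O_Wb
dms,education,E6,Graduate and above,146,142,97.2,139,95.2,97,66.1,30.6,O_S
dms,marital_status,M1,Single,1065,918,86.2,863,81.1,466,43.8,46.0,O_Wb
dms,marital_status,M2,Married or cohabiting,1876,1685,89.9,1473,78.5,886,47.2,39.8,O_Wb
dms,marital_status,M3,Other,133,63,47.2,54,40.7,17,13.1,68.0,C_G
dms,geographic_area,L1,Northern Area,974,868,89.2,775,79.6,442,45.4,43.0,O_Wb
dms,geographic_area,L2,Central Area,753,646,85.7,573,76.1,310,41.1,46.0,O_Wb
dms,geographic_area,L3,Southern Area,663,568,85.6,515,77.7,305,46.1,40.7,O_Wb
dms,geographic_area,L4,Eastern Area,87,76,86.9,74,84.6,37,41.9,50.5,O_Wb
dms,geographic_area,L5,Taipei City,365,341,93.5,304,83.4,194,53.3,36.1,O_Wb
dms,geographic_area,L6,Kaohsiung City,232,168,72.4,148,64.0,82,35.4,44.7,O_G
dms,personal_income_band,P1,<=450,651,520,79.9,474,72.9,265,40.7,44.2,O_G
dms,personal_income_band,P2,451-650,211,181,85.7,161,76.3,90,42.9,43.7,O_Wb
dms,personal_income_band,P3,651-950,501,460,91.9,414,82.7,240,47.8,42.2,O_Wb
dms,personal_income_band,P4,951-1250,433,413,95.4,369,85.1,219,50.5,40.7,O_S
dms,personal_income_band,P5,1251-1550,279,261,93.6,237,85.2,149,53.5,37.2,O_S
dms,personal_income_band,P6,1551-2250,219,216,98.6,192,88.0,150,68.6,22.0,O_S
dms,personal_income_band,P7,>=2251,140,137,97.8,124,88.5,62,44.4,49.9,O_S
dms,personal_income_band,P8,Don't know/no answer,641,479,74.8,419,65.3,195,30.4,53.5,O_G
dms,family_income_band,F1,No income or unstable,104,88,84.9,70,67.1,39,37.8,43.7,O_G
dms,family_income_band,F2,<=650,156,120,76.9,106,67.8,53,33.8,50.1,O_G
dms,family_income_band,F3,651-1250,478,398,83.2,347,72.6,178,37.3,48.6,O_G
dms,family_income_band,F4,1251-1850,561,501,89.2,462,82.3,257,45.8,44.3,O_Wb
dms,family_income_band,F5,1851-2450,445,412,92.6,379,85.1,239,53.6,37.0,O_S
dms,family_income_band,F6,2451-3050,316,296,93.5,274,86.9,176,55.6,36.0,O_S
dms,family_income_band,F7,3051-4650,295,280,94.8,253,85.9,164,55.8,35.1,O_S
dms,family_income_band,F8,>=4651,155,147,94.8,135,86.9,89,57.5,33.8,O_S
dms,family_income_band,F9,Don't know/no answer,563,425,75.5,364,64.6,174,30.9,52.2,O_G
dms,computer_ownership,C1,Yes,2787,2496,89.6,2259,81.0,1305,46.8,42.2,O_Wb
dms,computer_ownership,C2,No,286,170,59.5,132,46.0,65,22.7,50.8,D_G
dms,internet_access,I1,Yes,2154,1965,91.2,1816,84.3,1114,51.7,38.6,O_Wb
dms,internet_access,I2,No,919,701,76.3,574,62.5,255,27.8,55.5,O_G
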