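service,variable,item_id,label,n,aware_count,aware_pct,want_count,want_pct,adopt_count,adopt_pct,gap_pct,region_code
dhcs,total,T,Total,3074,1563,50.9,2139,69.6,150,4.9,93.0,O_G
dhcs,gender,G1,Male,1518,806,53.1,1055,69.5,84,5.5,92.1,O_G
dhcs,gender,G2,Female,1556,757,48.7,1084,69.7,66,4.3,93.9,P_G
dhcs,age_band,A1,15-24,509,250,49.1,366,71.9,31,6.1,91.5,P_G
dhcs,age_band,A2,25-34,621,318,51.2,440,70.8,32,5.1,92.8,O_G
dhcs,age_band,A3,35-44,568,315,55.5,415,73.1,23,4.0,94.5,O_G
dhcs,age_band,A4,45-54,565,334,59.2,432,76.5,23,4.1,94.6,O_G
dhcs,age_band,A5,55-64,367,173,47.2,246,67.1,15,4.1,93.9,P_G
dhcs,age_band,A6,>=65,444,173,39.0,239,53.9,27,6.0,88.9,P_G
dhcs,education,E1,Below primary school,384,120,31.3,196,51.2,15,4.0,92.3,P_G
dhcs,education,E2,Junior high school,249,114,45.7,154,61.5,8,3.1,95.0,P_G
dhcs,education,E3,Senior high school,1014,520,51.3,711,70.1,44,4.4,93.8,O_G
dhcs,education,E4,Junior college,434,262,60.4,330,76.1,20,4.5,94.0,O_G
dhcs,education,E5,University,847,451,53.3,636,75.1,55,6.4,91.4,O_G
dhcs,education,E6,Graduate and above,146,96,65.8,113,77.5,8,5.7,92.6,O_G
dhcs,marital_status,M1,Single,1065,541,50.8,765,71.8,62,5.8,92.0,O_G
dhcs,marital_status,M2,Married or cohabiting,1876,989,52.7,1325,70.6,86,4.6,93.5,O_G
dhcs,marital_status,M3,Other,133,34,25.1,49,37.0,2,1.7,95.3,C_G
dhcs,geographic_area,L1,Northern Area,974,502,51.5,689,70.8,53,5.4,92.4,O_G
dhcs,geographic_area,L2,Central Area,753,410,54.4,536,71.2,44,5.8,91.8,O_G
dhcs,geographic_area,L3,Southern Area,663,323,48.8,443,66.7,29,4.4,93.5,P_G
dhcs,geographic_area,L4,Eastern Area,87,46,52.2,70,80.6,3,3.4,95.7,O_G
dhcs,geographic_area,L5,Taipei City,365,192,52.6,270,74.1,10,2.6,96.4,O_G
dhcs,geographic_area,L6,Kaohsiung City,232,91,39.4,131,56.5,12,5.1,91.0,P_G
dhcs,personal_income_band,P1,<=450,651,277,42.6,422,64.8,33,5.1,92.1,P_G
dhcs,personal_income_band,P2,451-650,211,117,55.6,146,69.0,13,6.2,91.0,O_G
dhcs,personal_income_band,P3,651-950,501,258,51.5,358,71.4,24,4.8,93.3,O_G
dhcs,personal_income_band,P4,951-1250,433,228,52.7,332,76.7,23,5.4,93.0,O_G
dhcs,personal_income_band,P5,1251-1550,279,174,62.6,206,74.0,15,5.3,92.9,O_G
dhcs,personal_income_band,P6,1551-2250,219,135,61.5,178,81.2,14,6.2,92.4,O_G
dhcs,personal_income_band,P7,>=2251,140,93,66.6,112,79.6,12,8.7,89.0,O_G
dhcs,personal_income_band,P8,Don't know/no answer,641,280,43.7,387,60.4,16,2.5,95.8,P_G
dhcs,family_income_band,F1,No income or unstable,104,40,38.3,60,57.7,1,0.6,99.0,P_G
dhcs,family_income_band,F2,<=650,156,71,45.3,92,58.7,5,3.2,94.6,P_G
dhcs,family_income_band,F3,651-1250,478,210,44.0,330,69.2,24,5.0,92.8,P_G
dhcs,family_income_band,F4,1251-1850,561,320,57.0,416,74.1,26,4.7,93.7,O_G
dhcs,family_income_band,F5,1851-2450,445,246,55.3,325,73.0,29,6.4,91.2,O_G
dhcs,family_income_band,F6,2451-3050,316,171,54.2,237,74.9,17,5.5,92.7,O_G
dhcs,family_income_band,F7,3051-4650,295,182,61.8,232,78.7,22,7.6,90.4,O_G
dhcs,family_income_band,F8,>=4651,155,87,56.2,113,72.8,12,8.0,89.1,O_G
dhcs,family_income_band,F9,Don't know/no answer,563,236,41.9,334,59.3,14,2.4,95.9,P_G
dhcs,computer_ownership,C1,Yes,2787,1473,52.9,2026,72.7,143,5.1,92.9,O_G
dhcs,computer_ownership,C2,No,286,90,31.4,114,39.7,6,2.3,94.3,C_G
dhcs,internet_access,I1,Yes,2154,1192,55.3,1615,75.0,125,5.8,92.3,O_G
dhcs,internet_access,I2,No,919,371,40.4,524,57.0,25,2.7,95.3,P_G
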