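,liver,spleen,kidneys,red_marrow,heart_content,bladder_content,remainder
adrenals,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
brain,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
breasts,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
gallbladder_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
lower_large_intestine_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
small_intestine_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
stomach_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
upper_large_intestine_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
heart_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.09594848469577821,0.0005680745955593967,0.001849459294397604
kidneys,0.0005279532031339496,0.0005706041998629133,0.2863304990360978,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.000605902032
liver,0.06077524154759411,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.000605902032
lungs,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
muscle,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
ovaries,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
pancreas,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
red_marrow,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.045103191581907585,0.0005558792903727988,0.0005680745955593967,0.000605902032
skeleton,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.011127207154299197,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
skin,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
spleen,0.0005279532031339496,0.5914902749741889,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.000605902032
thymus,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
thyroid,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
urinary_bladder_wall,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.2211634745955594,0.001849459294397604
uterus,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
lens_of_eyes,0.0005279532031339496,0.0005706041998629133,0.0005605902494741783,0.0005386279542991972,0.0005558792903727988,0.0005680745955593967,0.001849459294397604
total_body,0.0017824108319999998,0.0017824108319999998,0.0017824108319999998,0.0017824108319999998,0.0017824108319999998,0.0017824108319999998,0.0017824108319999998
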